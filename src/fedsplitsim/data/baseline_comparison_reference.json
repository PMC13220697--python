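{
  "final_accuracy": {"centralized": 0.9881, "federated": 0.8494},
  "total_energy_kj": {"centralized": 5.93, "federated": 3.84},
  "computation_kj": {"centralized": 1.66, "federated": 0.86},
  "communication_kj": {"centralized": 3.8, "federated": 0.06},
  "total_tflops": {"centralized": 5.52, "federated": 1.23},
  "total_time_s": {"centralized": 639.79, "federated": 1066.26}
}
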