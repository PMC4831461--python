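{"omega": 0.3, "F": 0.0, "h": 1.0, "v_rr": 1.0, "u_rr": 1.0, "q0": 0.001, "qk": 0.1, "max_generations": 100000}
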