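# umbrella window metadata: path center(Å) spring
#! energy_unit: kT
#! bias_convention: half-k
#! n_rows: 2
toy_a.dat 1 2
toy_b.dat 2 2
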