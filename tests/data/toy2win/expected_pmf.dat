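# PMF: z(Å) W(kT)
#! n_rows: 6
#! zero_convention: bulk
0.25 0.017954498775747396
0.75 0.2933806174532938
1.25 0.2774959864842419
1.75 0.31502237890105267
2.25 0.2705572819196522
2.75 0.0
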