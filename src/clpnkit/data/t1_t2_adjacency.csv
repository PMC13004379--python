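predictor,PHYS1,PHYS2,PHYS3,PHYS4,PHYS5,PHYS6,PHYS7,PHYS8,PHYS9,PHYS10,PHYS11,PHYS12,PHYS13,PHYS14,PHYS15,PHYS16,PHYS17,PHYS18,PHYS19,COGS1,COGS2,COGS3,COGS4,COGS5,PSYS1,PSYS2,PSYS3,PSYS4,PSYS5,PSYS6,PSYS8
PHYS1,1.15,1,1,1,1,1.03,1.01,1,1,1,1,1,1.01,1,1,1,1,1,1,1.01,1.01,1.03,1,1,1,1,1,1,1,1,1
PHYS2,1,1.14,1.02,1.04,1,1.02,1,1.01,1.01,1.01,1,1.01,1,1.01,1,1,1,1.02,1.01,1,1.02,1,1,1.01,1,1.01,1,1,1,1,1
PHYS3,1,1.02,1.12,1,1,1,1,1,1,1,1.02,1,1,1,1,1,1,1,1,1.03,1.02,1,1,1,1,1,1.01,1,1,1.03,1
PHYS4,1,1,1,1.13,1,1,1,1,1,1.03,1,1,1,1,1,1,1,0.99,1,1,1,1,1,1,1,1,1,1,1,1,1
PHYS5,1,1,1,1,1.15,1,1,1,1,1.01,1,1,1,1,1,1,1,1,1.01,1,1,1,1,1,1,1,1,1,1,1,1
PHYS6,1.09,1.02,1,1.01,1,1.19,1,1,1,1,1,1,1,1,1.01,1,1,1,1,1.02,1,1.03,1,1,1,1.02,1,1,1,1,1
PHYS7,1.05,1.02,1.02,1,1,1.03,1.24,1.02,1,1,1.02,1.01,1,1,1,1.01,1,1,1,1.04,1,1.02,1.02,1.01,1,1,1,1,1,1,1
PHYS8,1,1,1.01,1.04,1,1.02,1,1.25,1,1.01,1,1,1,1.01,1,1,1,1,1,1.01,1.02,1.01,1,1.01,1,1,1,1,1,1,1
PHYS9,1,1,1,1,1.01,1,1,1,1.27,1,1.02,1,1,1,1,1,1,1,1.01,1,1,1,1.01,1,1,1,1,1,1,1.01,1
PHYS10,1,1.03,1,1.05,1,1,1,1.03,1,1.14,1.02,1,1.02,1.01,1,1,1,1,1.01,1,1,1.01,1,1,1.03,1,1,1,1.01,1.03,1
PHYS11,1,1,1.01,1,1,1,1.02,1.02,1.02,1.05,1.19,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1.03,1
PHYS12,1,1,1,1,1.06,1,1,1,1,1.02,1,1.14,1,1.03,0.99,1.05,1,1,1.02,1,1.07,1,1,1,0.99,1,1,1,1,1,1
PHYS13,1,1,1,1,1,1.02,1.01,1.03,1,1,1,1,1.17,1,1.04,1,1,1.02,1,1,1.02,1,1,1,1,1,1,1,1,1,1
PHYS14,1,1,1.06,1,1,1,1,0.99,1,1,1,1,1.02,1.06,1,1,1.03,1,1,1.03,1,1,1,1,1.05,1,1,1.04,1,1,1
PHYS15,1,0.99,1,1,1.01,1,1,1,1,1.01,1,1,1,1,1.22,1,1,0.99,1,1,0.99,1,1,1,1,0.99,1,1,1,0.99,1
PHYS16,1,1,1.05,1,1,1.06,1.01,1.04,1,1,1.02,1.01,1.01,1,0.98,1.21,1.02,1,1.01,1,1,1,1,1,0.99,1,1,1,1,1,1
PHYS17,1,1,1,1.01,1.02,1.02,1,1,1,1,1,1.01,1.03,1,1,1.02,1.21,1,1,1,1,1,1,1,1,1,1,1,1,1,1
PHYS18,1.01,1,1,0.99,1,1,1,1.01,1,1,1,1,1,1,1,1,1,1.23,1,1,1,1,1,1,1,1,1,1,1,1,1
PHYS19,1,1.03,1,1.07,1,1.01,1,1,1.02,1,1,1.04,1.05,1,1,1,1,1.07,1.17,1,1,1,1,1,1,1,1,1,1,1.02,1
COGS1,1,1,1.01,1,1,1,1,1.03,1,1.01,1.05,1,1.01,1,1.03,1,1,1.01,1,1.17,1,1,1,1,1,1.03,1,1,1,1,1
COGS2,1.02,1,1,1,1,1.05,1,1,1.01,1.01,1.01,1,1.02,1,1,1,1,1.05,1,1.03,1.21,1.11,1.06,1.04,1.02,1.05,1.03,1.02,1.04,1.04,1
COGS3,1.06,1.01,1.01,1.03,1,1.05,1.01,1.01,1.01,1.01,1,1,1,1,1.04,1,1.02,1.07,1,1,1.07,1.16,1,1,1.01,1,1,1.03,1,1.01,1
COGS4,1.02,1,1,1,1,1.01,1.04,0.99,0.98,1,1,1,1,1.02,1.01,1,1.01,1,1,1.06,1,1.1,1.05,1,1,1,1,1,1,1,1
COGS5,1.02,1,1.09,1,1.1,1,1.06,0.94,1,1,1.02,1.04,1,1.02,1,1.01,1.08,1.01,1.01,1.07,1.14,1,1.2,1.27,1.01,1.12,1.08,1.04,1.04,1.03,1.04
PSYS1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1.17,1,1.02,1.08,1,1.03,1.04
PSYS2,1,1,1,1,1,1,1,1,1,1.03,1,1,1,1,1,1,1,0.96,1,1.02,1,1,1.03,1,1,1.05,1,1.02,1.03,1.01,1
PSYS3,1.01,1.04,1,1.05,1,1.11,1,1,1,1,1,1,1.01,1,1,1,1,1,1,1,1,1,1,1,1,1.05,1.08,1.01,1,1,1.01
PSYS4,1,1.02,1,1,1,1,1,1.02,1,1,1,1,1,1,1,1,1,1.01,1,1,1,1,1,1,1,1,1,1.05,1,1.04,1
PSYS5,1,1.06,1,1,1,1,1,1.01,1,1,1.01,1.01,1.01,1,1,1,1,1,1.03,1,1,1,1,1.01,1,1,1.01,1,1.14,1.02,1
PSYS6,1.05,1,1,1,1,1,1.01,1.03,1,1,1,1,1.02,1,1.01,1,1.02,1,1,1,1,1.02,1,1,1.02,1.02,1.02,1.04,1.03,1.17,1.07
PSYS7,1,1,1,1,1,1,1,0.94,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1.02,1,1,1.04,1,1,1
PSYS8,1.01,1,1,1.01,1,1,1,1.11,1,1,1.01,1,1.01,1,1,1,1,1,1,1,1,1,1,1,1,1,1.02,1,1,1,1.11
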