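sample_id,HI_adult,HI_adult_rey,HI_child,HI_child_rey,TCR_adult,TCR_adult_rey,TCR_child,TCR_child_rey
CFA1,0.56,0.02,5.12,0.21,1.0e-4,5.0e-16,2.3e-4,1.2e-15
CBA2,0.51,0.01,4.68,0.12,1.1e-4,2.9e-16,2.5e-4,6.7e-16
CFA3,0.62,0.02,5.69,0.23,1.2e-4,5.4e-16,2.7e-4,1.3e-15
CBA4,0.49,0.02,4.42,0.17,1.1e-4,3.9e-16,2.5e-4,9.2e-16
CFA5,1.71,0.02,15.9,0.16,2.7e-4,3.8e-16,6.2e-4,8.8e-16
CBA6,0.46,0.01,4.21,0.12,8.3e-5,2.8e-16,1.9e-4,6.5e-16
CFA7,0.86,0.02,7.96,0.23,1.5e-4,5.5e-16,3.3e-4,1.3e-15
CBA8,0.39,0.01,3.54,0.08,8.7e-5,1.8e-16,2.0e-4,4.3e-16
CFA9,0.36,0.01,3.27,0.13,6.3e-5,3.1e-16,1.4e-4,7.3e-16
CBA10,0.29,0.01,2.60,0.09,5.2e-5,2.0e-16,1.2e-4,4.7e-16
Mean,0.63,0.017,5.74,0.15,1.1e-4,3.6e-16,2.6e-4,8.4e-16
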