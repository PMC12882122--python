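ring_type,conformation,theta1,theta2,theta3
cyclohexane,chair,32.2,32.2,32.2
cyclohexane,half-chair,16.1,-20.9,53.0
cyclohexane,boat,-30.8,-31.7,64.4
cyclohexane,twist-boat,-0.7,-57.4,58.2
cyclohexane,flat,0.1,-0.0,0.4
cyclopentane,half-chair,-33.2,36.2,
cyclopentane,envelope,-25.9,40.7,
cyclopentane,flat,-0.2,0.2,
benzene,flat,0.0,0.0,0.0
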