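metal	kd_molar	enabled
Mn2+		false
Fe2+		false
Co2+		false
Ni2+	6.0e-14	true
Zn2+	2.2e-11	true
Cu1+		false
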