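metal	kd_molar	enabled
Mn2+	3.1e-09	true
Fe2+	2.5e-08	true
Co2+		false
Ni2+		false
Zn2+		false
Cu1+		false
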