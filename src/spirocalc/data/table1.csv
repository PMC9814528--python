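name,bridge_atom,nucleophile,halogen_z,amine_r1,amine_r2,measured_pkcycl,calculated_pkcycl,calculated_pkcycl_alt,printed_error,kanh_pka,kaoh_pka,substituent,position,footnote
HMRG,O,OH,H,H,H,8.1,7.9,11.3,0.2,4.6,15.4,,,calculated with 5 explicit waters (3-water value in alt)
AMRG,O,NH,H,H,H,6.2,6.2,10.1,0.0,4.6,,,,calculated with 5 explicit waters (3-water value in alt)
HMTMR,O,OH,H,Me,Me,9.5,9.5,,0.0,4.9,15.4,,,
AMTMR,O,NH,H,Me,Me,7.8,8.1,,0.3,4.9,,,,
HMRB,O,OH,H,Et,Et,9.2,9.3,,0.1,4.9,15.4,,,
AMRB,O,NH,H,Et,Et,8.2,8.1,,0.1,4.9,,,,
HMSiR,SiMe2,OH,H,Me,Me,5.7,6.2,,0.5,4.9,15.4,,,
AMSiR,SiMe2,NH,H,Me,Me,4.2,4.8,,0.6,4.9,,,,
HMDiMeR,O,OH,H,H,Me,8.9,9.2,,0.3,4.9,15.4,,,asymmetric amines; monoalkylated anilinium pKa assumed
HMDiEtR,O,OH,H,H,Et,9.3,8.8,,0.5,4.9,15.4,,,asymmetric amines; monoalkylated anilinium pKa assumed
HMJR,O,OH,H,H,julolidine,10.3,10.7,,0.4,4.9,15.4,,,ring-fused (julolidine) amine
HMDiMeFR,O,OH,F,H,Me,8.2,8.3,,0.1,4.9,15.4,,,
HMDiMeCR,O,OH,Cl,H,Me,7.7,7.3,,0.4,4.9,15.4,,,
HMJFR,O,OH,F,H,julolidine,9.8,9.8,,0.0,4.9,15.4,,,ring-fused (julolidine) amine
HMJCR,O,OH,Cl,H,julolidine,9.1,8.7,,0.4,4.9,15.4,,,ring-fused (julolidine) amine
HMSiR620h,SiMe2,OH,H,H,Me,5.0,4.8,,0.2,4.9,15.4,,,
HMJSiR,SiMe2,OH,H,H,julolidine,6.6,7.1,,0.4,4.9,15.4,,,published error column prints 0.4; |6.6-7.1| recomputes to 0.5
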