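name,bridge_atom,nucleophile,halogen_z,amine_r1,amine_r2,measured_pkcycl,calculated_pkcycl,calculated_pkcycl_alt,printed_error,kanh_pka,kaoh_pka,substituent,position,footnote
HMRR,SiMe2,OH,H,H,H,8.4,8.6,,,4.6,15.4,,,five-membered-ring designed red fluorophore (SiR600 scaffold); calculated value is the pre-synthesis prediction
HMRY,CMe2,OH,H,H,H,9.2,9.0,,,4.6,15.4,,,five-membered-ring designed yellow fluorophore (CR550 scaffold); calculated value is the pre-synthesis prediction
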