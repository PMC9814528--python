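name,bridge_atom,nucleophile,halogen_z,amine_r1,amine_r2,measured_pkcycl,calculated_pkcycl,calculated_pkcycl_alt,printed_error,kanh_pka,kaoh_pka,substituent,position,footnote
3F-HMRG,O,OH,H,H,H,8.0,8.1,,,4.6,15.4,F,3',
4F-HMRG,O,OH,H,H,H,,8.3,,,4.6,15.4,F,4',no measured value published
5F-HMRG,O,OH,H,H,H,,7.4,,,4.6,15.4,F,5',no measured value published
6F-HMRG,O,OH,H,H,H,,8.1,,,4.6,15.4,F,6',no measured value published
3M-HMRG,O,OH,H,H,H,6.6,6.1,,,4.6,15.4,Me,3',
4M-HMRG,O,OH,H,H,H,,8.1,,,4.6,15.4,Me,4',no measured value published
5M-HMRG,O,OH,H,H,H,8.2,7.9,,,4.6,15.4,Me,5',
6M-HMRG,O,OH,H,H,H,,7.2,,,4.6,15.4,Me,6',no measured value published
3CF3-HMRG,O,OH,H,H,H,5.3,5.3,,,4.6,15.4,CF3,3',
4CF3-HMRG,O,OH,H,H,H,,7.1,,,4.6,15.4,CF3,4',no measured value published
5CF3-HMRG,O,OH,H,H,H,,7.4,,,4.6,15.4,CF3,5',no measured value published
6CF3-HMRG,O,OH,H,H,H,,7.6,,,4.6,15.4,CF3,6',no measured value published
HMRG,O,OH,H,H,H,8.1,7.9,,,4.6,15.4,H,,unsubstituted parent
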