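{
 "compounds": [
  {
   "name": "benzaldehyde",
   "shift_sigma": 0.1,
   "resonances": [
    {"shift_ppm": 10.05, "weight": 1, "couplings": []},
    {"shift_ppm": 7.91, "weight": 2, "couplings": [{"J_hz": 7.5, "N": 1}]},
    {"shift_ppm": 7.66, "weight": 1, "couplings": [{"J_hz": 7.5, "N": 2}]},
    {"shift_ppm": 7.55, "weight": 2, "couplings": [{"J_hz": 7.5, "N": 2}]}
   ]
  },
  {
   "name": "methyl cinnamate (E)",
   "shift_sigma": 0.1,
   "resonances": [
    {"shift_ppm": 7.74, "weight": 1, "couplings": [{"J_hz": 16.0, "N": 1}]},
    {"shift_ppm": 7.56, "weight": 2, "couplings": []},
    {"shift_ppm": 7.41, "weight": 3, "couplings": []},
    {"shift_ppm": 6.47, "weight": 1, "couplings": [{"J_hz": 16.0, "N": 1}]},
    {"shift_ppm": 3.84, "weight": 3, "couplings": []}
   ]
  },
  {
   "name": "methyl cinnamate (Z)",
   "shift_sigma": 0.1,
   "resonances": [
    {"shift_ppm": 7.63, "weight": 2, "couplings": []},
    {"shift_ppm": 7.36, "weight": 3, "couplings": []},
    {"shift_ppm": 6.98, "weight": 1, "couplings": [{"J_hz": 12.6, "N": 1}]},
    {"shift_ppm": 5.98, "weight": 1, "couplings": [{"J_hz": 12.6, "N": 1}]},
    {"shift_ppm": 3.73, "weight": 3, "couplings": []}
   ]
  }
 ]
}
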