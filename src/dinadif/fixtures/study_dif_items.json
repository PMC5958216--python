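{
 "dif_items": [
  2,
  12,
  14,
  16,
  24,
  26
 ],
 "selection_seed": 11,
 "note": "six frozen DIF items, three per complexity stratum"
}
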