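{
 "bands": [
  ["Z-disk", 1, 2200],
  ["I-band", 2201, 14200],
  ["A-band", 14201, 33818],
  ["M-band", 33819, 35991]
 ],
 "tk": [33819, 34073]
}
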