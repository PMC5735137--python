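[
 {"name": "1000G", "total_alleles": 5008,
  "variant_alleles": {"0.0005": 231, "0.0001": 0}},
 {"name": "ESP6500", "total_alleles": 13006,
  "variant_alleles": {"0.0005": 1895, "0.0001": 820}},
 {"name": "ExAC", "total_alleles": 106210,
  "variant_alleles": {"0.0005": 11811, "0.0001": 6651}}
]
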