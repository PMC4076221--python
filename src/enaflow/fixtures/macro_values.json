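{
  "description": "Published endpoint values for the Beijing currency network, 1985 and 2010. TST in billion yuan per year (current and constant 1985 prices); ascendency A and development capacity C in billion yuan-bits per year.",
  "year_start": 1985,
  "year_end": 2010,
  "span_years": 25,
  "TST_current": [118.0, 9940.0],
  "TST_constant": [118.0, 1496.0],
  "A": [63.0, 710.0],
  "C": [514.0, 7127.0],
  "growth_rate_TST_current_pct": 19.41,
  "growth_rate_TST_constant_pct": 10.7,
  "growth_rate_A_pct": 10.2,
  "growth_rate_C_pct": 11.09,
  "ami_range_bits": [0.45, 0.58],
  "stage_boundaries": [1985, 1987, 1992, 2002, 2005, 2007, 2010],
  "stage_tst_percent": [90.9, 179.8, 82.1, 185.9, 56.3, 352.3],
  "stage_ami_percent": [9.1, -79.8, 17.9, -85.9, 43.7, -252.3]
}
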