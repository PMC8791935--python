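# Placeholder short-term mortality relative risks per pollutant.
#
# These are NOT the values used in any published analysis: the original
# study cites multi-country literature without printing numbers, so every
# real application must supply its own risk configuration.  The values
# below are round, plausible magnitudes kept only so the pipeline runs
# end-to-end out of the box.
#
# rr / ci refer to the stated increment (µg/m³); internally converted to a
# per-µg/m³ log relative risk.
no2:
  rr: 1.0070
  ci: [1.0050, 1.0090]
  increment: 10.0
o3:
  rr: 1.0040
  ci: [1.0030, 1.0050]
  increment: 10.0
pm25:
  rr: 1.0065
  ci: [1.0045, 1.0085]
  increment: 10.0
pm10:
  rr: 1.0040
  ci: [1.0030, 1.0050]
  increment: 10.0
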