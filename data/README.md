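# Worked-example data

The worked example and one acceptance test analyse the National Toxicology
Program (NTP) long-term carcinogenicity bioassay of methyleugenol in female
B6C3F1 mice (NTP technical report TR-491): 50 mice per group received 0, 37,
75 or 150 mg/kg for 105 weeks, with presence/absence recorded per animal for
each tumor classification.

The per-animal indicator table is published alongside the study's reanalyses
but is not redistributed with this package.  To run the worked example on the
real data, place it here as

    data/ntp_methyleugenol.csv

with a header row and columns

    id,dose,t24,t26,t27,t28,t29,t36,t41,t42,t59,t71,...

where `dose` is in mg/kg (0/37/75/150) and each `t..` column holds a 0/1
tumor indicator (200 rows, one per mouse).  Columns for tumor classes other
than the ten listed are accepted; the standard analysis filters to classes
with more than five events in total (`--min-events 5`).

Without this file the examples fall back to simulated data and the
NTP-specific acceptance test reports failure.
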