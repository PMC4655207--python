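# Synthetic normative table of end-diastolic wall thickness by body surface
# area, used for pediatric z-scores.  These values are a constructed,
# plausible lookup (mean thickness rising smoothly with BSA), NOT a
# published pediatric normative dataset; replace via configuration with a
# real reference table for clinical use.
bsa_m2,mean_thickness_mm,sd_thickness_mm
0.50,5.0,0.80
0.75,5.5,0.85
1.00,6.0,0.90
1.25,6.5,0.95
1.50,7.0,1.00
1.75,7.5,1.05
2.00,8.0,1.10
2.25,8.5,1.15
2.50,9.0,1.20
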