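# Bioenergetic constants for converting stress-test parameters to a
# common ATP-rate unit (JATP, pmol ATP/min).
#
# p_o_ratio: ATP synthesized per O atom reduced by oxidative
#   phosphorylation (literature consensus ~2.45 for mixed substrates);
#   OCR counts O2 molecules, so the oxidative conversion is
#   atp_linked * 2 * p_o_ratio.
# mph_to_pmol_h: buffering conversion from the instrument's mpH/min to
#   pmol H+/min; depends on assay medium buffering power and well
#   geometry -- calibrate per platform.
# atp_per_lactate: glycolytic ATP per exported lactate (one H+ per
#   lactate at physiological pH).
p_o_ratio: 2.45
mph_to_pmol_h: 10.0
atp_per_lactate: 1.0
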