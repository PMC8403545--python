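# Secondary-structure strings (H helix, E strand, C coil), 98 positions each.
# scaffold_actual / scaffold_predicted: wild-type 1YN3 chain; designed: the
# common backbone assignment shared by all ten designs; predicted_N:
# sequence-based prediction for design N.
scaffold_actual	CEEEEEEEEECCCCCCEEEEEEECCCCEEEHHHHHHHHHHHHHHHHCCCHHHHHHCCCEEEEEEECCCCEEEEECCCCCCCCCEEEHHHEEEEEEEEC
scaffold_predicted	CCCCCEEEEECCCEEEEEEEEEECCCCCCCHHHHHHHHHHHHHHCCCCCHHHHHHCCEEEEEEEEECCCEEEEECCCCCCCCCCCCHHHCEEEEEEEC
designed	CEEEEEEEECCCCCCCEEEEEEECCCCEEEHHHHHHHHHHHHHHHHCCCHHHHHCCCCEEEEEEECCCCEEEEECCCCCCCCCEEEHHHEEEEEEEEC
predicted_1	CCCCCCEEEECCCCCCEEEEECCCCCCCCCHHHHHHHHHHHHHHHHCCCHHHHHHCCEEEEEEEEECCCEEEEECCCCCCCCCCCCHHHCEEEEEEEC
predicted_2	CCCCCCEEEECCCCEEEEEEEEECCCCCCCHHHHHHHHHHHHHHHHCCCHHHHHHCEEEEEEEEECCCCEEEEECCCCCCCCCCCCHHHCEEEEEEEC
predicted_3	CCCCCCEEEECCCCEEEEECEECCCCCCCCHHHHHHHHHHHHHHHHCCCHHHHHHCCEEEEEEEECCCCEEEEECCCCCCHHCCCCHHHCEEEEEEEC
predicted_4	CCCCCEEEEECCCCCEEEEEEEECCCCCCCHHHHHHHHHHHHHHHHCCCHHHHHHCEEEEEEEEECCCCEEEEECCCCCCHHHCCCHHHCCEEEEEEC
predicted_5	CCEECEEEECCCCCCCEEEEEECCCCCCCCHHHHHHHHHHHHHHCCCCCHHHHHHCCEEEEEEEECCCCEEEEECCCCCCHHCCCCHHHCEEEEEEEC
predicted_6	CCCCCEEEECCCCCCEEEEEEEECCCCCCCHHHHHHHHHHHHHHCCCCCHHHHHHCCEEEEEEEECCCCEEEEECCCCCCCCCCCCHHHCCEEEEEEC
predicted_7	CCCCCCEEECCCCCCCCCCCEEECCCCCCCHHHHHHHHHHHHHHCCCCCHHHHHHCEEEEEEEEECCCCEEEEECCCCCCCCCCCCHHHCCEEEEEEC
predicted_8	CCCCCCEEECCCCCCCEEEEEEECCCCCCCHHHHHHHHHHHHHHHCCCCHHHHHHHCEEEEEEEECCCCEEEEECCCCCCCCCCCCHHHCEEEEEEEC
predicted_9	CCEECCEEECCCCCCCEEEEEEECCCCCCCHHHHHHHHHHHHHHCCCCCHHHHHHCCEEEEEEEECCCCEEEEECCCCCCCCCCCCHHHCEEEEEEEC
predicted_10	CCEECCEEECCCCCCCEEEEEEECCCCCCCHHHHHHHHHHHHHHCCCCCHHHHHHCCEEEEEEEECCCCEEEEECCCCCCCCCCCCHHHCEEEEEEEC
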