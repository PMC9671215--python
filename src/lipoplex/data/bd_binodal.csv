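# Synthetic piecewise-linear digitization of the Bligh-Dyer
# water/methanol/chloroform one-phase/two-phase binodal (weight %),
# ordered from the water-rich to the chloroform-rich end and constrained
# through the critical composition (30/15/55 w/w). Replaceable by a
# user-supplied digitization with the same schema.
w_water,w_methanol,w_chloroform
98.0,0.0,2.0
76.5,15.0,8.5
54.0,28.0,18.0
39.6,34.0,26.4
29.25,35.0,35.75
26.8,33.0,40.2
30.0,15.0,55.0
23.5,6.0,70.5
9.9,1.0,89.1
2.0,0.0,98.0
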