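mz,cancer,glands,stroma
150.7,0.152,,
155.2,-0.012,,
155.7,,,0.201
179.2,0.065,,
180.7,,-0.071,
186.7,0.060,,
187.2,0.028,,
187.7,0.005,,
189.2,,0.034,
196.7,,,0.414
197.7,,-0.009,0.028
198.2,,,0.041
200.2,,-0.231,
202.7,0.159,,
204.2,0.252,,
207.2,,,0.026
214.7,,,0.185
215.2,-0.096,,0.251
217.2,,,0.173
233.7,,-0.146,0.983
244.7,,-0.193,
246.7,,,0.192
247.2,,,0.306
250.2,,,0.028
264.7,0.008,,
265.2,0.008,,
265.7,0.002,,
266.2,0.011,,
267.2,0.002,,
277.2,-0.069,0.033,
282.2,-0.026,,
306.2,0.118,,
307.2,0.174,,
307.7,0.174,,
308.2,0.110,,
331.2,0.136,,
331.7,0.025,,
332.2,0.202,,
332.7,0.051,-0.072,
333.2,0.133,,
333.7,,-0.017,
335.7,0.077,,
344.2,,-0.112,
346.2,0.213,,
347.2,,-0.082,
352.7,,-0.182,0.063
359.2,,-0.180,
359.7,,-0.058,
367.7,0.091,,
376.7,,-0.001,
381.7,,-0.112,
382.7,,-0.129,
386.2,0.082,,
391.2,,0.065,
418.7,0.099,,
420.7,,-0.009,
421.7,,-0.279,
428.2,0.010,,
441.7,0.287,,
448.7,,-0.230,
452.2,,0.024,
456.7,,-0.311,
498.7,,-0.023,
499.2,0.241,,
499.7,0.074,,
503.2,0.313,,
503.7,0.049,,
506.7,,,0.138
556.2,,0.309,
574.7,,-0.316,
578.2,-0.097,0.173,
614.7,0.007,-0.088,
615.2,0.028,,
625.7,,-0.073,
626.2,0.016,,
646.7,,-0.161,
648.2,,-0.205,
648.7,,-0.210,
649.2,0.245,-0.131,
649.7,0.536,-0.038,
650.2,0.224,,
650.7,0.012,-0.411,
669.7,,-0.036,
710.8,,-0.072,
724.8,0.069,,
725.8,0.205,,
726.8,,-0.063,
737.8,,-0.210,
738.3,0.067,-0.064,
738.8,0.130,-0.148,
746.8,0.018,,
747.3,0.132,,
747.8,0.284,,
752.8,,-0.034,
760.8,,-0.110,
775.8,0.057,,
778.8,0.000,-0.202,
780.8,,-0.001,
788.8,0.030,,
792.8,,0.231,
796.8,0.038,,
797.8,0.143,,
871.8,,-0.139,
872.3,,-0.121,
872.8,,-0.125,
885.8,0.004,,
887.8,0.044,,
892.8,,-0.068,
896.8,,-0.025,
904.8,,-0.049,
906.8,0.223,-0.223,
907.8,,-0.034,
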