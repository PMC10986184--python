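participant_id,group,region,gm_w,mean_wm_w
p00,CN,r0,-1.039984,0.164598
p00,CN,r1,0.940565,-0.316283
p00,CN,r2,-1.30218,0.03221
p00,CN,r3,-0.316243,0.03286
p00,CN,r4,-0.853044,0.195996
p00,CN,r5,0.777792,0.082247
p00,CN,r6,1.127241,0.173027
p00,CN,r7,-0.859292,0.093679
p00,CN,r8,-0.958883,0.192631
p01,CN,r0,-0.184862,-0.149221
p01,CN,r1,1.222541,-0.001719
p01,CN,r2,-0.428328,-0.090765
p01,CN,r3,0.532309,0.081569
p01,CN,r4,0.412733,0.091057
p01,CN,r5,2.141648,-0.024522
p01,CN,r6,-0.512243,-0.185611
p01,CN,r7,0.615979,0.236785
p01,CN,r8,-0.113947,-0.178939
p02,CN,r0,0.650593,0.044496
p02,CN,r1,0.543154,-0.240479
p02,CN,r2,0.232161,-0.09337
p02,CN,r3,0.218689,0.057174
p02,CN,r4,0.223596,0.018818
p02,CN,r5,0.067579,-0.063821
p02,CN,r6,0.631288,-0.396165
p02,CN,r7,-0.319671,-0.227337
p02,CN,r8,-0.638878,-0.197867
p03,CN,r0,-0.865831,0.391922
p03,CN,r1,-1.68287,0.106778
p03,CN,r2,0.162753,0.346368
p03,CN,r3,0.711227,0.404247
p03,CN,r4,-0.348725,0.121309
p03,CN,r5,0.857976,0.21172
p03,CN,r6,-1.275686,-0.040687
p03,CN,r7,-0.919452,0.29609
p03,CN,r8,0.142426,0.366611
p04,CN,r0,0.15854,0.065786
p04,CN,r1,-0.309347,0.017987
p04,CN,r2,-0.661926,-0.156556
p04,CN,r3,-0.381738,-0.314708
p04,CN,r4,0.486972,-0.143359
p04,CN,r5,0.012494,0.032436
p04,CN,r6,0.446531,0.082385
p04,CN,r7,-0.098485,-0.151702
p04,CN,r8,-0.079718,-0.403946
p05,amnestic,r0,-1.8227,-0.662332
p05,amnestic,r1,-0.100226,-0.506181
p05,amnestic,r2,-0.878163,-0.127474
p05,amnestic,r3,-0.856264,-0.238065
p05,amnestic,r4,-1.433618,-0.472844
p05,amnestic,r5,-1.450022,-0.500875
p05,amnestic,r6,0.340308,-0.635306
p05,amnestic,r7,-0.065576,-0.274766
p05,amnestic,r8,-1.09415,-0.69381
p06,amnestic,r0,-1.029493,-0.125005
p06,amnestic,r1,-0.478148,0.192923
p06,amnestic,r2,-0.739356,-0.353029
p06,amnestic,r3,-0.320724,-0.070839
p06,amnestic,r4,0.859188,0.146577
p06,amnestic,r5,-0.143129,0.19203
p06,amnestic,r6,-1.688763,-0.352232
p06,amnestic,r7,-1.426576,-0.281269
p06,amnestic,r8,-1.876686,-0.112285
p07,amnestic,r0,-1.970806,-0.494114
p07,amnestic,r1,-0.186486,0.019373
p07,amnestic,r2,1.496731,0.569178
p07,amnestic,r3,-0.085591,-0.338088
p07,amnestic,r4,-2.632046,-0.290355
p07,amnestic,r5,-1.312941,-0.32144
p07,amnestic,r6,-1.112097,-0.250459
p07,amnestic,r7,0.56598,-0.056645
p07,amnestic,r8,-0.658635,-0.393155
p08,amnestic,r0,-0.986308,-0.440864
p08,amnestic,r1,1.26793,-0.223713
p08,amnestic,r2,0.48274,-0.412442
p08,amnestic,r3,-1.684944,-0.679021
p08,amnestic,r4,-1.225226,-0.023527
p08,amnestic,r5,-1.321387,-0.289216
p08,amnestic,r6,-1.402927,-0.277122
p08,amnestic,r7,-0.115049,-0.391734
p08,amnestic,r8,-0.540763,-0.525421
p09,non-amnestic,r0,-0.954983,-0.454609
p09,non-amnestic,r1,-1.777938,-0.240807
p09,non-amnestic,r2,1.079091,-0.014764
p09,non-amnestic,r3,-0.618638,-0.125415
p09,non-amnestic,r4,0.806002,-0.024733
p09,non-amnestic,r5,-0.910927,0.015294
p09,non-amnestic,r6,-0.071244,0.168363
p09,non-amnestic,r7,-0.316766,-0.403324
p09,non-amnestic,r8,-1.868159,0.047644
p10,non-amnestic,r0,-0.679519,-0.072449
p10,non-amnestic,r1,0.961444,-0.085944
p10,non-amnestic,r2,-1.394727,0.075637
p10,non-amnestic,r3,-0.894605,-0.014043
p10,non-amnestic,r4,-0.663443,0.072989
p10,non-amnestic,r5,0.907482,0.149265
p10,non-amnestic,r6,0.143939,-0.339969
p10,non-amnestic,r7,-0.548718,-0.153994
p10,non-amnestic,r8,-1.718813,-0.254586
p11,non-amnestic,r0,0.415903,-0.482125
p11,non-amnestic,r1,-0.469369,-0.384502
p11,non-amnestic,r2,-0.827673,-0.115781
p11,non-amnestic,r3,0.038115,0.02041
p11,non-amnestic,r4,-0.654506,-0.441667
p11,non-amnestic,r5,-0.723859,-0.259528
p11,non-amnestic,r6,-0.323427,-0.49287
p11,non-amnestic,r7,-0.40951,-0.237234
p11,non-amnestic,r8,2.017474,0.286648
p12,non-amnestic,r0,-0.787383,-0.683666
p12,non-amnestic,r1,-1.090707,-0.352122
p12,non-amnestic,r2,0.705854,-0.417335
p12,non-amnestic,r3,-1.154146,-0.849776
p12,non-amnestic,r4,-0.662666,-0.593483
p12,non-amnestic,r5,-1.029439,-0.585714
p12,non-amnestic,r6,-0.594263,-0.727073
p12,non-amnestic,r7,-1.967045,-0.059501
p12,non-amnestic,r8,-1.787423,-0.690337
p13,non-amnestic,r0,2.405067,0.033629
p13,non-amnestic,r1,-0.868249,0.074388
p13,non-amnestic,r2,1.228698,-0.023539
p13,non-amnestic,r3,-0.745278,0.171382
p13,non-amnestic,r4,-0.065234,-0.004913
p13,non-amnestic,r5,-0.633823,-0.250148
p13,non-amnestic,r6,-0.738174,-0.036794
p13,non-amnestic,r7,-0.26783,-0.056955
p13,non-amnestic,r8,-0.028461,0.275803
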