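n,sample_id,age_Ga,facies,h_wt,h_wt_sd,c_wt,c_wt_sd,hc_printed,ash,aromaticity,aromaticity_sd,fwhm_g,fwhm_g_sd,fwhm_d1,fwhm_d1_sd,r1,r1_sd,la_angstrom,la_sd
1,Clarno,0.05,n.m.,2.82,0.2,44.8,0.4,0.76,,66,3,97,3,249,12,0.60,0.02,4.9,0.1
2,Rhynie,0.4,n.m.,2.13,0.2,31.3,0.4,0.81,41,72,3,85,6,232,10,0.67,0.11,5.5,0.1
3,Zalesie Nowe,0.42,p.p. to p.a.,4.47,0.2,57.6,0.4,0.93,,58,3,79,2,207,3,0.84,0.04,5.1,0.2
4,Zdanow,0.42,p.p. to p.a.,2.64,0.2,69.4,0.4,0.46,,98,1,67,4,224,6,0.86,0.03,5.7,0.2
5,Dobra,0.42,lower g.s.,1.75,0.2,74.5,0.4,0.28,,99,1,57,2,162,6,0.97,0.05,6.6,0.8
6,Gunflint (n.6),1.9,lower g.s.,2.80,0.2,66.0,0.4,0.51,17,98,3,66,4,178,6,0.77,0.06,5.4,0.6
7,Gunflint (n.7),1.9,lower g.s.,1.2,0.2,26.4,0.4,0.55,41,,,62,3,180,3,0.57,0.01,,
8,Gunflint (n.8),1.9,lower g.s.,1.69,0.2,27.2,0.4,0.75,50,92,,52,2,175,11,0.47,0.01,6,
9,Rietgat,2.65,lower g.s.,0.77,0.2,17.3,0.4,0.53,62,,,68,4,82,4,1.20,0.03,,
10,Farrel Quartzite GGR2,3.0,lower to mid g.s.,0.68,0.2,19.4,0.4,0.42,70,,,60,7,66,3,1.39,0.04,,
11,Farrel Quartzite GRW10,3.0,lower to mid g.s.,2.76,0.2,60.6,0.4,0.55,13,,,69,3,81,4,1.25,0.04,,
12,Farrel Quartzite ORW9,3.0,lower to mid g.s.,0.67,0.2,21.1,0.4,0.38,60,,,65,4,66,6,1.58,0.09,8,2
13,Farrel Quartzite GFWEX1-1b,3.0,lower to mid g.s.,0.84,0.2,32.9,0.4,0.31,58,,,58,2,61,1,1.58,0.04,,
14,Farrel Quartzite MGTKS1up,3.0,lower to mid g.s.,0.99,0.2,40.2,0.4,0.30,43,,,65,4,64,4,1.45,0.04,7.5,0.5
15,Josefsdal,3.3,g.s.,0.43,0.1,13.2,0.3,0.39,81,,,56,4,59,3,2.17,0.34,9.4,0.8
16,Middle Marker,3.4,g.s.,1.94,0.2,17.6,0.3,1.32,54,98,1,60,2,61,2,1.70,0.10,9,0.4
17,Dresser,3.5,p.p. to lower g.s.,2.92,0.2,52.2,0.4,0.67,22,57,3,57,3,87,5,1.35,0.09,6.2,0.3
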