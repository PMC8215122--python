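study_id,condition,n_patients,n_controls,age_mean,age_sd,ctrl_age_mean,ctrl_age_sd,duration_mean,duration_sd,duration_is_median,hba1c_mean,hba1c_sd,q1,q2,q3,q4,q5,q6,q7,q8,q9,q10,q11,q12
kaufmann,T1DM,30,19,14.3,4.0,13,3.2,5.6,3.8,0,8.4,0.9,1,1,1,1,1,1,1,1,1,0.5,0,0
liu,T1DM,21,21,9.3,2.1,9.4,1.1,0.6,0.1,0,11.2,2.2,1,1,1,1,1,1,1,1,1,0,0,0
marzelli,T1DM,142,68,7.0,1.7,7,1.8,2.9,2.0,0,7.9,0.9,1,1,1,1,1,1,1,1,1,1,0,0
musen,T1DM,82,36,32.6,3.2,31.3,5.1,20.3,3.6,0,7.8,1.3,1,1,1,1,1,1,1,1,1,1,0,0
nunley,T1DM,95,135,49.1,6.7,48.7,7.3,40.9,6.2,0,,,1,1,1,1,1,1,1,1,1,1,0,0
perantie,T1DM,108,51,12.6,2.7,12.3,2.7,5.7,2.9,0,8.4,1.0,1,1,1,1,1,1,1,1,1,1,0,0
wessels,T1DM,31,21,40.8,5.9,36.3,7.9,26.8,8.3,0,8.0,1.1,1,1,1,1,1,1,1,1,1,1,0,0
chen_a,T2DM,16,16,61.2,7.8,59.6,6.1,13.2,5.6,0,8.4,1.7,1,1,1,1,1,1,1,1,1,1,0,0
chen_b,T2DM,23,24,60.8,8.3,57.0,7.5,9.0,4.8,0,8.6,2.2,1,1,1,1,1,1,1,1,1,1,0,0
cui,T2DM,40,41,60.5,6.9,57.9,6.5,8.9,5.0,0,7.7,1.6,1,1,1,1,1,1,1,1,1,0,0,0
fang,T2DM,35,32,32.1,5.3,34.1,4.8,1,,0,10.4,2.4,1,1,1,1,1,1,1,1,1,1,1,0
ferreira,T2DM,24,27,58.6,8.6,59.9,5.9,8.0,7.9,0,10.0,2.8,1,1,1,1,1,1,1,1,0.5,0,0,0
garcia_casares,T2DM,25,25,60.0,4.6,57.8,5.4,11.25,7.9,0,6.7,0.8,1,1,1,1,1,1,1,1,1,1,0,0
moran,T2DM,350,363,67.8,6.9,72.1,7.2,7,,1,7.2,1.2,1,1,1,1,1,1,1,1,1,1,0,0
nouwen,T2DM,14,19,16.1,1.5,16.4,1.7,2.7,2.5,0,8.1,2.3,1,1,1,1,1,1,1,1,1,1,0,0
redel,T2DM,20,20,16.7,2.0,16.7,2.6,2.8,2.1,0,7.9,2.2,1,1,1,1,1,1,1,1,1,0,0,0
wang_a,T2DM,23,23,53.1,9.6,53.9,9.2,7,,0,8.3,1.4,1,1,1,1,1,1,1,1,1,0.5,0,0
wang_b,T2DM,17,17,54.8,8.3,54.4,7.9,,,0,,,1,1,1,1,1,1,1,1,1,1,1,1
zhang_a,T2DM,53,29,54.2,8.5,55.48,,7.3,5.7,0,7.6,1.5,1,1,1,1,1,1,1,1,1,1,0,0
zhang_b,T2DM,26,26,51.9,10.7,48.2,6.7,9.2,7.1,0,,,1,1,1,1,1,1,1,1,1,1,0,0
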