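label,group1,mean1,sem1,n1,group2,mean2,sem2,n2,t_reported,df_reported
op1_amplitude_25w,db/+,126.31,4.42,14,db/db,83.89,7.92,11,-4.939,23
op2_amplitude_25w,db/+,174.63,4.53,14,db/db,135.81,13.44,11,-3.008,23
sum_ops_amplitude_25w,db/+,446.37,10.24,14,db/db,353.10,34.77,11,-2.847,23
op4_amplitude_9w,db/+,31.80,4.00,14,db/db,49.89,5.56,11,2.709,23
onl_thickness_25w,db/+,65.78,2.72,7,db/db,53.60,2.02,6,-3.488,11
inl_thickness_25w,db/+,44.40,1.93,7,db/db,30.85,1.55,6,-5.347,11
photoreceptor_density_25w,db/+,428.32,33.82,7,db/db,316.41,14.35,6,-2.865,11
cone_count_25w,db/+,49.41,3.58,7,db/db,28.76,4.10,6,-3.815,11
axon_terminals_25w,db/+,134.21,12.13,7,db/db,55.75,8.75,6,-5.080,11
dendritic_boutons_25w,db/+,45.88,3.87,7,db/db,14.69,1.91,5,-6.356,10
basal_respiration_25w,db/+,122.76,7.93,5,db/db,75.29,6.75,7,-4.554,10
maximal_respiration_25w,db/+,147.87,11.98,5,db/db,94.41,14.11,7,-2.725,10
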