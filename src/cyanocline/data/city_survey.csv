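city,n_populations,n_plants,mean_hcn_freq,beta_hcn,sig_hcn,beta_ac,sig_ac,beta_li,sig_li,quad_hcn,quad_li,fixed_excluded,new_survey
Montreal,49,969,0.447,-0.057,0,NA,NA,NA,NA,0,0,0,0
Toronto,121,2379,0.323,0.283,1,0.218,1,0.271,1,0,0,0,0
Boston,44,876,0.197,0.119,1,NA,NA,NA,NA,0,0,0,0
Detroit,40,593,0.320,0.052,0,NA,NA,NA,NA,0,0,0,1
Cleveland,40,594,0.269,0.093,0,0.067,0,0.019,0,0,0,0,1
New York,48,946,0.191,0.145,1,0.204,1,0.033,0,0,0,0,0
Pittsburgh,40,590,0.221,0.069,0,NA,NA,NA,NA,0,0,0,1
Philadelphia,40,588,0.199,-0.031,0,NA,NA,NA,NA,0,0,0,1
Baltimore,39,584,0.216,0.031,0,0.065,0,0.031,0,0,0,0,1
Cincinnati,40,588,0.207,0.035,0,NA,NA,NA,NA,0,0,0,1
Washington,45,658,0.236,0.175,1,0.326,1,-0.062,0,0,1,0,1
Norfolk,40,585,0.395,0.337,1,0.358,1,0.038,0,0,0,0,1
Charlotte,40,589,0.498,0.070,0,-0.077,0,-0.003,0,1,1,0,1
Atlanta,45,654,0.421,0.362,1,0.263,1,0.161,1,0,1,0,1
Jacksonville,35,500,0.872,0.272,1,0.202,1,0.292,1,1,1,0,1
Tampa,15,215,0.991,-0.029,0,NA,NA,NA,NA,0,0,1,1
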