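compound_id,cns_mpo,bbb_score,neg_logs,mpa,pl,clogd_74,herg,exp_pass_herg,exp_pass_neg_logs,exp_pass_cns_mpo,exp_pass_bbb_score,exp_pass_mpa,exp_n_pass
HR66,3.7033190476190456,4.1044458624858216,5.363309490631889,68.34500000000001,42.43400000000001,4.761553599507147,4.2,True,True,True,True,False,4
HR67,3.7033190476190456,4.1044458624858216,5.363309490631889,56.660000000000004,42.43400000000001,4.761553599507147,4.29,True,True,True,True,True,5
HR68,3.7033190476190456,4.1044458624858216,5.363309490631889,64.83500000000001,42.43400000000001,4.761553599507147,4.38,True,True,True,True,False,4
HR69,3.4841761904761905,4.0768898896407535,5.628107180141989,70.305,44.26900000000001,5.069973599507147,4.47,True,True,True,True,False,4
HR70,3.4841761904761905,4.0768898896407535,5.628107180141989,66.5725,44.26900000000001,5.069973599507147,4.56,True,True,True,True,False,4
HR71,3.7642761904761888,4.163475117618553,5.164753580141989,69.58500000000001,44.26900000000001,4.437068395665064,4.65,True,True,True,True,False,4
HR72,3.7642761904761888,4.163475117618553,5.164753580141989,57.587500000000006,44.26900000000001,4.437068395665064,4.74,True,True,True,True,True,5
HR73,3.7642761904761888,4.163475117618553,5.164753580141989,56.135000000000005,44.26900000000001,4.437068395665064,4.83,True,True,True,True,True,5
HR74,3.5098733333333314,4.132275628296955,5.430644865711202,64.985,46.104000000000006,4.745488395665064,4.92,True,True,True,True,False,4
HR75,3.5098733333333314,4.132275628296955,5.430644865711202,60.660000000000004,46.104000000000006,4.745488395665064,5.01,True,True,True,True,False,4
HR76,3.5098733333333314,4.132275628296955,5.430644865711202,57.89250000000001,46.104000000000006,4.745488395665064,5.1,True,True,True,True,True,5
HR77,3.6596499999999974,4.296118994242892,5.4519262657112035,56.720000000000006,46.104000000000006,4.779268395665065,,,True,True,True,True,4
HR78,3.642833333333331,4.132275628296955,5.197115265711202,62.44000000000001,46.104000000000006,4.479568395665065,5.28,True,True,True,True,False,4
HR79,3.642833333333331,4.132275628296955,5.197115265711202,58.96000000000001,46.104000000000006,4.479568395665065,4.2,True,True,True,True,True,5
HR80,3.642833333333331,4.132275628296955,5.197115265711202,70.485,46.104000000000006,4.479568395665065,4.29,True,True,True,True,False,4
HR81,3.226797619047619,3.479979716127001,6.432958235314404,67.28000000000002,49.70400000000001,5.914753599507148,5.8,False,True,True,False,False,2
HR82,3.226797619047619,3.479979716127001,6.432958235314404,78.00500000000001,49.704,5.914753599507148,4.47,True,True,True,False,False,3
HR83,3.226797619047619,3.528267246561085,6.432958235314404,72.2425,49.70400000000001,5.913928807167323,5.65,False,True,True,False,False,2
HR84,3.383983333333333,4.132275628296955,5.589770265711203,60.265,46.104000000000006,4.998068395665065,4.65,True,True,True,True,False,4
HR85,3.383983333333333,4.132275628296955,5.589770265711203,56.54750000000001,46.104000000000006,4.998068395665065,4.74,True,True,True,True,True,5
HR86,3.383983333333333,4.132275628296955,5.589770265711203,66.05250000000001,46.104000000000006,4.998068395665064,4.83,True,True,True,True,False,4
HR87,3.383983333333333,4.132275628296955,5.589770265711203,55.407500000000006,46.104000000000006,4.998068395665064,4.92,True,True,True,True,True,5
HR88,3.402907142857141,3.379402529329633,5.2606020203891894,71.4625,43.07100000000001,4.467153599507147,5.01,True,True,True,False,False,3
HR89,3.6090571428571416,3.9321324691665978,5.000853020389188,68.08250000000001,43.003000000000014,4.055400000000003,5.1,True,True,True,False,False,3
HR90,3.6090571428571416,3.9321324691665978,5.000853020389188,58.02250000000001,43.003000000000014,4.055400000000003,5.19,True,True,True,False,True,4
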