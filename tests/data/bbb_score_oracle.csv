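aro_rings,heavy_atoms,mwhbn,tpsa,pka,c_aro,c_ha,c_mwhbn,c_tpsa,c_pka,weighted_score
3,28,0.2516234910109791,68.29,4.5,0.691115,0.8243256102308276,0.9570058049416555,0.5232933944571785,0.21381951185630615,4.104445862485821
2,20,0.3,75.0,8.0,1.0,0.9996299446839393,0.8407387417310197,0.47645342779745775,0.9615143400369571,4.6944020828938635
1,12,0.1,40.0,9.0,0.816016,0.7857450206734365,0.7307190899277589,0.7207751614919775,0.9978819323568047,4.638330944727432
0,5,0.05,0.0,3.0,0.336376,0.0,0.0,0.0,0.0,0.336376
6,50,0.5,200.0,12.0,0.0,0.0,0.0,0.0,0.0,0.0
4,45,0.45,120.0,11.0,0.199399,0.15489057736638998,0.28591591934457233,0.16232548447593242,0.7243574431620435,1.469993146916135
2,35,0.25,90.0,7.0,1.0,0.523063577425665,0.9597769451133441,0.3717441133569494,0.8171874246846824,4.1148109341519215
3,30,0.35,110.0,5.0,0.691115,0.7452369395303974,0.6702508718757788,0.2321316941029381,0.33565527675869694,3.07381927392929
1,10,0.15,30.0,10.0,0.816016,0.6459147334880838,0.9325145658612195,0.7905813711189831,0.9161690276624843,4.899949838349121
2,25,0.2,60.0,6.5,1.0,0.9218342248302313,0.9996180353732458,0.5811627422379662,0.712652124394131,4.939912824563097
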