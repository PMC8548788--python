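batch,district,similarity,score,ranking
S1,"Baishan City, Jilin Province",0.958,2.408,3
S2,"Baishan City, Jilin Province",0.982,0.956,13
S3,"Bozhou City, Anhui Province",0.952,1.519,9
S4,"Bozhou City, Anhui Province",0.951,2.500,2
S5,"Changbai Mountain City, Jilin Province",0.882,0.551,15
S6,"Chengdu City, Sichuan Province",0.919,1.797,6
S7,"Hulun Buir City, Inner Mongolia Autonomous Region",0.989,1.600,7
S8,"Jinan City, Shandong Province",0.963,1.533,8
S9,"Kunming City, Yunnan Province",0.975,1.011,11
S10,"Laiyang City, Shandong Province",0.832,0.971,12
S11,"Laiyang City, Shandong Province",0.829,0.676,14
S12,"Lanxi County, Heilongjiang Province",0.952,1.368,10
S13,"Linyi City, Shandong Province",0.961,2.223,4
S14,"Nanjing City, Jiangsu Province",0.984,2.647,1
S15,"Yuncheng City, Shandong Province",0.964,2.071,5
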