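site_id,station_id,site_label,collapse,starred,p4_species,p1_dir,p1_tag,p2_dir,p2_tag,p3_dir,p3_tag,p4_dir,p4_tag,p5_dir,p5_tag,p6_dir,p6_tag
1,1,Bermuda,1,0,thalassia,D,none,-,,-,,D,none,D,none,I,none
1,2,Bermuda,1,0,thalassia,D,none,-,,-,,D,none,D,none,D,none
2,4,USA-Long Key,0,0,thalassia,-,,-,,-,,-,,n,none,n,none
2,5,USA-Long Key,0,1,thalassia,I,N,-,,-,,-,,I,N,I,none
3,6,Bahamas-San Salvador,0,0,thalassia,n,none,n,none,-,,n,none,-,,-,
3,7,Bahamas-San Salvador,0,0,thalassia,n,none,D,none,-,,n,none,-,,-,
4,8,Cuba-Cayo Coco,0,1,thalassia,D,T,-,,-,,I,NT,n,none,D,T
4,9,Cuba-Cayo Coco,0,1,thalassia,D,T,-,,-,,I,NT,n,none,D,T
5,10,Mexico-Puerto Morelos,0,1,thalassia,n,none,I,NT,I,NT,I,NT,I,N,I,none
5,11,Mexico-Puerto Morelos,0,1,thalassia,I,N,n,none,I,NT,I,NT,n,none,I,none
5,12,Mexico-Puerto Morelos,0,1,thalassia,n,none,I,NT,-,,I,NT,I,N,n,none
5,13,Mexico-Puerto Morelos,1,1,thalassia,I,N,n,none,n,none,I,NT,n,none,n,none
7,15,Cayman Islands-Grand Cayman,0,0,thalassia,-,,-,,-,,-,,I,N,D,T
8,17,Jamaica-Discovery Bay,0,1,thalassia,I,N,-,,-,,I,NT,I,N,-,
10,21,Puerto Rico-La Parguera,0,1,thalassia,I,N,-,,I,NT,I,NT,n,none,n,none
10,22,Puerto Rico-La Parguera,0,0,thalassia,n,none,-,,n,none,I,NT,n,none,n,none
12,25,Belize-Twin Cays,0,1,thalassia,n,none,I,NT,n,none,I,NT,I,N,D,T
12,26,Belize-Carrie Bow Cay,0,0,thalassia,n,none,n,none,n,none,I,NT,n,none,I,none
13,29,Colombia-Isla Providencia,0,0,thalassia,n,none,n,none,-,,n,none,n,none,n,none
13,30,Colombia-Isla Providencia,0,0,thalassia,n,none,D,none,-,,n,none,n,none,n,none
13,31,Colombia-Isla Providencia,0,0,thalassia,n,none,n,none,-,,n,none,D,T,n,none
14,33,Barbados-St. Lawrence,1,1,other,n,none,I,NT,-,,I,NT,n,none,D,T
14,34,Barbados-St. Lawrence,1,1,other,n,none,I,NT,-,,I,NT,n,none,-,
15,37,Colombia-Isla San Andres,0,0,thalassia,n,none,n,none,-,,n,none,-,,I,none
15,38,Colombia-Isla San Andres,0,0,thalassia,n,none,n,none,-,,n,none,-,,n,none
17,41,Colombia-Chengue Bay,0,0,thalassia,n,none,-,,-,,n,none,n,none,n,none
17,42,Colombia-Chengue Bay,0,0,thalassia,n,none,-,,-,,n,none,n,none,n,none
18,43,Tobago-Bon Accord Lagoon,0,0,thalassia,n,none,-,,-,,n,none,n,none,n,none
18,44,Tobago-Bon Accord Lagoon,0,0,thalassia,n,none,-,,-,,n,none,D,T,n,none
20,47,Venezuela-Morrocoy,0,1,thalassia,I,N,-,,-,,I,NT,I,N,I,none
20,48,Venezuela-Morrocoy,0,1,thalassia,I,N,-,,-,,I,NT,I,N,I,none
21,49,Costa Rica-Cahuita,0,1,thalassia,D,T,-,,-,,n,none,D,T,D,T
21,50,Costa Rica-Cahuita,0,0,thalassia,-,,-,,-,,-,,D,T,n,none
22,51,Panama-Isla de Colon,0,0,thalassia,I,N,-,,-,,-,,n,none,n,none
22,52,Panama-Isla de Colon,0,0,thalassia,I,N,-,,-,,-,,n,none,I,none
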