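patient_id,age,gender,years_diagnosed,medication,dominant_hand
1,65,Male,5,"Levodopa carbidopa 1/2 tab, Pramipexol 1 mg 1/2 tab",Right
2,75,Male,8,"Levodopa carbidopa 1/2 tab, Pramipexol 1 mg 1/2 tab",Right
3,60,Male,4,None,Right
4,73,Female,7,Levodopa carbidopa,Right
5,68,Female,10,Levodopa carbidopa 1/4 tab,Right
6,68,Female,9,"Levodopa, Pramipexol",Right
7,77,Female,12,Levodopa carbidopa,Right
8,62,Male,2,Pramipexol 0.25 mg,Right
9,66,Male,6,Pramipexol 0.25 mg,Right
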