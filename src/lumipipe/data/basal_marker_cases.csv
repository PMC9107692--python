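case_id,ihc_subtype,molecular_subtype,basal_marker,ki67_pct,pr_pct,er_pct,grade,p53,immune_group,tils_level,ror_class,recurrence,ck56_pos,egfr_pos,ck14_pos,ambiguous_digits
1,LumB,Basal,positive,80,0,1,3,P,istrong,high,high,yes/m,1,1,1,0
2,LumB,Basal,positive,60,30,2,3,P,istrong,high,medium,no,1,1,0,0
3,LumB,Basal,positive,60,0,1,2,P,iweak,low,medium,no,0,1,0,0
4,LumB,Basal,positive,60,5,0,2,N,istrong,high,high,yes/m,1,1,1,1
5,LumB,Basal,positive,90,0,10,3,P,iweak,low,high,no,0,1,0,0
6,LumB,Basal,positive,40,10,5,3,P,istrong,high,high,yes/m,1,1,0,0
7,LumB,LumA,positive,30,90,90,2,N,iweak,low,medium,no,0,1,0,0
8,LumA,LumA,positive,6,60,80,2,N,iweak,low,low,yes/m,0,1,0,1
9,LumB,LumA,positive,10,0,95,1,N,iweak,low,medium,no,0,1,0,1
10,LumB,LumB,positive,20,95,95,2,N,iweak,low,medium,no,0,1,0,0
11,LumA,LumA,positive,3,100,100,1,P,iweak,low,low,no,0,1,0,0
12,LumA,LumA,positive,10,30,60,1,N,iweak,low,low,yes/m,0,1,0,0
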