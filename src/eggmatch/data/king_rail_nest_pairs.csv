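# Published King Rail nest pairs: distances (m), estimated first-egg dates,
# nest fates and last active dates as printed in the field study.  The match
# criteria columns encode the published qualitative criteria as minimal
# counts: every pair had at least two eggs match (n_multi = 2); Tier I pairs
# additionally showed symmetrical matching (n_symmetrical = 1); Tier II pairs
# reached the top-8 tally threshold (top_k_tally = 4).
tier_published,nest_a,nest_b,distance_m,first_egg_a,first_egg_b,fate_a,fate_b,last_active_a,last_active_b,inferred_link_published,n_symmetrical,n_multi,top_k_tally
I,20-20,20-21,91,5/4/2020,5/3/2020,H/D,H,6/2/2020,6/2/2020,CBP,1,2,4
I,16-17,17-22,33,4/27/2016,5/7/2017,H,H,5/25/2016,6/8/2017,returning_breeder,1,2,4
I,19-22,20-05,61,6/3/2019,4/22/2020,H,P,6/30/2019,5/22/2020,returning_breeder,1,2,4
IIa,16-29,19-05,1357,-,4/28/2019,P,H/D,6/7/2016,5/28/2019,returning_breeder,0,2,4
IIa,15-25,19-28,1319,6/2/2015,-,P/D,D,-,6/23/2019,returning_breeder,0,2,4
IIb,19-08,19-15,851,5/9/2019,5/27/2019,H/D,P/H,6/4/2019,6/22/2019,CBP,0,2,4
IIb,12-21,12-51,3305,4/21/2012,6/23/2012,P,P,5/13-15/2012?,7/15-17/2012?,renest,0,2,4
IIb,20-10,20-20,440,Early May,5/4/2020,D,H/D,5/17/2020,6/2/2020,CBP,0,2,4
IIb,14-03,14-04,623,4/9/2014,4/9/2014,H,H,5/12/2014,5/12/2014,CBP,0,2,4
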