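section,label,count
Totals,patients,832314
Totals,reports,1242518
Totals,raw_reports_all_soc,22375298
Totals,duplicates_removed_all_soc,3761306
Gender,F,504021
Gender,M,251228
Gender,unspecified,77065
Age,<18,29961
Age,18-44,113971
Age,45-64,186712
Age,>=65,180008
Age,unspecified,321662
Report year,2004,9605
Report year,2005,12298
Report year,2006,13522
Report year,2007,13681
Report year,2008,15162
Report year,2009,16755
Report year,2010,25465
Report year,2011,26470
Report year,2012,29281
Report year,2013,35555
Report year,2014,35595
Report year,2015,50057
Report year,2016,48343
Report year,2017,52526
Report year,2018,59067
Report year,2019,61143
Report year,2020,61923
Report year,2021,60668
Report year,2022,62655
Report year,2023,64832
Report year,2024,77711
Reporter,consumer,416491
Reporter,lawyer,15738
Reporter,unspecified,38857
Reporter,other-health-professional,80203
Reporter,pharmacist,96151
Reporter,physician,184874
Country,United States,523595
Country,Canada,43857
Country,United Kingdom,36371
Outcome,LT,20708
Outcome,HO,148981
Outcome,DS,42422
Outcome,DE,17839
Outcome,CA,4449
Outcome,RI,5789
Outcome,OT,425819
Time-to-Onset,0-30d,129323
Time-to-Onset,31-60d,14124
Time-to-Onset,61-90d,8543
Time-to-Onset,91-120d,6232
Time-to-Onset,121-150d,4563
Time-to-Onset,151-180d,3844
Time-to-Onset,181-360d,15217
Time-to-Onset,360d<,37462
Time-to-Onset,missing,613006
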