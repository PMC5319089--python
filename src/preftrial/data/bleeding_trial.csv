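arm,preference,treatment,outcome
choice,A,A,2.6857248614389224
choice,A,A,4.231755432390154
choice,A,A,5.777786003341385
choice,A,A,7.323816574292616
choice,A,A,8.869847145243845
choice,A,A,10.415877716195077
choice,A,A,11.961908287146308
choice,A,A,13.507938858097539
choice,A,A,15.05396942904877
choice,A,A,16.6
choice,A,A,18.146030570951233
choice,A,A,19.692061141902464
choice,A,A,21.238091712853695
choice,A,A,22.784122283804926
choice,A,A,24.330152854756157
choice,A,A,25.87618342570739
choice,A,A,27.42221399665862
choice,A,A,28.96824456760985
choice,A,A,30.514275138561082
choice,B,B,-5.703850681965475
choice,B,B,-4.543465613768928
choice,B,B,-3.3830805455723816
choice,B,B,-2.222695477375833
choice,B,B,-1.0623104091792852
choice,B,B,0.09807465901726253
choice,B,B,1.2584597272138094
choice,B,B,2.4188447954103576
choice,B,B,3.579229863606905
choice,B,B,4.739614931803453
choice,B,B,5.9
choice,B,B,7.060385068196548
choice,B,B,8.220770136393096
choice,B,B,9.381155204589643
choice,B,B,10.541540272786191
choice,B,B,11.701925340982738
choice,B,B,12.862310409179287
choice,B,B,14.022695477375834
choice,B,B,15.183080545572382
choice,B,B,16.343465613768927
choice,B,B,17.503850681965474
choice,none,A,0.4769503112632236
choice,none,A,1.2916343880239864
choice,none,A,2.1063184647847457
choice,none,A,2.9210025415455103
choice,none,A,3.7356866183062714
choice,none,A,4.550370695067036
choice,none,A,5.365054771827797
choice,none,A,6.179738848588562
choice,none,A,6.994422925349323
choice,none,A,7.8091070021100855
choice,none,A,8.623791078870848
choice,none,A,9.438475155631611
choice,none,A,10.253159232392372
choice,none,A,11.067843309153135
choice,none,A,11.882527385913898
choice,none,A,12.69721146267466
choice,none,A,13.511895539435423
choice,none,A,14.326579616196184
choice,none,A,15.141263692956947
choice,none,A,15.95594776971771
choice,none,A,16.770631846478473
choice,none,A,17.585315923239236
choice,none,A,18.4
choice,none,A,19.21468407676076
choice,none,A,20.029368153521524
choice,none,A,20.844052230282287
choice,none,A,21.65873630704305
choice,none,A,22.473420383803813
choice,none,A,23.288104460564576
choice,none,A,24.10278853732534
choice,none,A,24.9174726140861
choice,none,A,25.732156690846864
choice,none,A,26.546840767607627
choice,none,A,27.361524844368386
choice,none,A,28.17620892112915
choice,none,A,28.99089299788991
choice,none,A,29.805577074650675
choice,none,A,30.620261151411434
choice,none,A,31.4349452281722
choice,none,A,32.24962930493296
choice,none,A,33.06431338169372
choice,none,A,33.878997458454485
choice,none,A,34.69368153521525
choice,none,A,35.50836561197601
choice,none,A,36.32304968873677
choice,none,B,-4.410267138451519
choice,none,B,-4.01434590488554
choice,none,B,-3.6184246713195627
choice,none,B,-3.2225034377535833
choice,none,B,-2.8265822041876065
choice,none,B,-2.430660970621628
choice,none,B,-2.0347397370556504
choice,none,B,-1.6388185034896718
choice,none,B,-1.2428972699236942
choice,none,B,-0.8469760363577157
choice,none,B,-0.45105480279173715
choice,none,B,-0.055133569225759516
choice,none,B,0.34078766434021857
choice,none,B,0.7367088979061966
choice,none,B,1.1326301314721747
choice,none,B,1.5285513650381528
choice,none,B,1.9244725986041313
choice,none,B,2.320393832170109
choice,none,B,2.7163150657360875
choice,none,B,3.1122362993020656
choice,none,B,3.5081575328680437
choice,none,B,3.9040787664340217
choice,none,B,4.3
choice,none,B,4.695921233565978
choice,none,B,5.091842467131956
choice,none,B,5.4877637006979345
choice,none,B,5.883684934263912
choice,none,B,6.279606167829891
choice,none,B,6.675527401395868
choice,none,B,7.071448634961847
choice,none,B,7.467369868527825
choice,none,B,7.863291102093803
choice,none,B,8.25921233565978
choice,none,B,8.65513356922576
choice,none,B,9.051054802791736
choice,none,B,9.446976036357714
choice,none,B,9.842897269923693
choice,none,B,10.238818503489671
choice,none,B,10.63473973705565
choice,none,B,11.030660970621629
choice,none,B,11.426582204187607
choice,none,B,11.822503437753582
choice,none,B,12.218424671319562
choice,none,B,12.614345904885539
choice,none,B,13.010267138451518
random,,A,8.46581943144741
random,,A,8.829743621803768
random,,A,9.193667812160125
random,,A,9.557592002516483
random,,A,9.92151619287284
random,,A,10.2854403832292
random,,A,10.649364573585558
random,,A,11.013288763941915
random,,A,11.377212954298273
random,,A,11.74113714465463
random,,A,12.105061335010989
random,,A,12.468985525367348
random,,A,12.832909715723705
random,,A,13.196833906080062
random,,A,13.56075809643642
random,,A,13.924682286792779
random,,A,14.288606477149136
random,,A,14.652530667505495
random,,A,15.016454857861852
random,,A,15.38037904821821
random,,A,15.744303238574568
random,,A,16.108227428930924
random,,A,16.472151619287285
random,,A,16.836075809643642
random,,A,17.2
random,,A,17.563924190356357
random,,A,17.927848380712714
random,,A,18.291772571069075
random,,A,18.655696761425432
random,,A,19.01962095178179
random,,A,19.383545142138146
random,,A,19.747469332494504
random,,A,20.11139352285086
random,,A,20.475317713207218
random,,A,20.83924190356358
random,,A,21.203166093919936
random,,A,21.567090284276293
random,,A,21.93101447463265
random,,A,22.29493866498901
random,,A,22.65886285534537
random,,A,23.022787045701726
random,,A,23.386711236058083
random,,A,23.75063542641444
random,,A,24.114559616770798
random,,A,24.47848380712716
random,,A,24.842407997483516
random,,A,25.206332187839873
random,,A,25.57025637819623
random,,A,25.93418056855259
random,,B,-7.825000000000001
random,,B,-7.275
random,,B,-6.725000000000001
random,,B,-6.175000000000001
random,,B,-5.625
random,,B,-5.075000000000001
random,,B,-4.525
random,,B,-3.9750000000000014
random,,B,-3.4250000000000007
random,,B,-2.875000000000001
random,,B,-2.325000000000001
random,,B,-1.7750000000000012
random,,B,-1.2250000000000005
random,,B,-0.6750000000000007
random,,B,-0.1250000000000009
random,,B,0.4249999999999998
random,,B,0.9749999999999996
random,,B,1.5249999999999995
random,,B,2.0749999999999997
random,,B,2.6249999999999996
random,,B,3.175
random,,B,3.7249999999999996
random,,B,4.2749999999999995
random,,B,4.824999999999999
random,,B,5.375
random,,B,5.925
random,,B,6.475
random,,B,7.0249999999999995
random,,B,7.574999999999999
random,,B,8.125
random,,B,8.675
random,,B,9.225
random,,B,9.774999999999999
random,,B,10.325
random,,B,10.875
random,,B,11.425
random,,B,11.975000000000001
random,,B,12.525
random,,B,13.075
random,,B,13.625
random,,B,14.175
random,,B,14.725
random,,B,15.275
random,,B,15.825
random,,B,16.375
random,,B,16.925
random,,B,17.475
random,,B,18.025
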