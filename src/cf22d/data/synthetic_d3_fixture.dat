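# SYNTHETIC dispersion fixture table (H, C, N, O, Si, Ar).
# Covalent radii are Pyykko single-bond values; the R0 and C6 entries are
# synthetic stand-ins with physically plausible magnitudes, generated by a
# smooth combining rule -- they are NOT the published D3 reference data.
[covalent_radii]
H 0.32
C 0.75
N 0.71
O 0.63
Si 1.16
Ar 0.96
[r0]
H H 2.1800
H C 2.5000
H N 2.4100
H O 2.3400
H Si 2.8100
H Ar 2.6900
C C 2.8200
C N 2.7300
C O 2.6600
C Si 3.1300
C Ar 3.0100
N N 2.6400
N O 2.5700
N Si 3.0400
N Ar 2.9200
O O 2.5000
O Si 2.9700
O Ar 2.8500
Si Si 3.4400
Si Ar 3.3200
Ar Ar 3.2000
[c6_reference]
cn H 0 1
cn C 0 1 2 3 4
cn N 0 1 2 3
cn O 0 1 2
cn Si 0 1 2 3 4
cn Ar 0
c6 H H 0 0 7.600000
c6 H H 0 1 7.209993
c6 H H 1 0 7.209993
c6 H H 1 1 6.840000
c6 H C 0 0 19.317350
c6 H C 0 1 18.326047
c6 H C 0 2 17.884391
c6 H C 0 3 17.634247
c6 H C 0 4 17.473200
c6 H C 1 0 18.326047
c6 H C 1 1 17.385615
c6 H C 1 2 16.966623
c6 H C 1 3 16.729316
c6 H C 1 4 16.576533
c6 H N 0 0 13.866506
c6 H N 0 1 13.154923
c6 H N 0 2 12.837890
c6 H N 0 3 12.658331
c6 H N 1 0 13.154923
c6 H N 1 1 12.479856
c6 H N 1 2 12.179092
c6 H N 1 3 12.008747
c6 H O 0 0 10.853571
c6 H O 0 1 10.296601
c6 H O 0 2 10.048454
c6 H O 1 0 10.296601
c6 H O 1 1 9.768214
c6 H O 1 2 9.532801
c6 H Si 0 0 48.145612
c6 H Si 0 1 45.674938
c6 H Si 0 2 44.574176
c6 H Si 0 3 43.950730
c6 H Si 0 4 43.549345
c6 H Si 1 0 45.674938
c6 H Si 1 1 43.331051
c6 H Si 1 2 42.286776
c6 H Si 1 3 41.695323
c6 H Si 1 4 41.314536
c6 H Ar 0 0 22.106108
c6 H Ar 1 0 20.971695
c6 C C 0 0 49.100000
c6 C C 0 1 46.580350
c6 C C 0 2 45.457767
c6 C C 0 3 44.821963
c6 C C 0 4 44.412621
c6 C C 1 0 46.580350
c6 C C 1 1 44.190000
c6 C C 1 2 43.125024
c6 C C 1 3 42.521847
c6 C C 1 4 42.133512
c6 C C 2 0 45.457767
c6 C C 2 1 43.125024
c6 C C 2 2 42.085714
c6 C C 2 3 41.497074
c6 C C 2 4 41.118097
c6 C C 3 0 44.821963
c6 C C 3 1 42.521847
c6 C C 3 2 41.497074
c6 C C 3 3 40.916667
c6 C C 3 4 40.542991
c6 C C 4 0 44.412621
c6 C C 4 1 42.133512
c6 C C 4 2 41.118097
c6 C C 4 3 40.542991
c6 C C 4 4 40.172727
c6 C N 0 0 35.245283
c6 C N 0 1 33.436612
c6 C N 0 2 32.630792
c6 C N 0 3 32.174395
c6 C N 1 0 33.436612
c6 C N 1 1 31.720755
c6 C N 1 2 30.956287
c6 C N 1 3 30.523311
c6 C N 2 0 32.630792
c6 C N 2 1 30.956287
c6 C N 2 2 30.210243
c6 C N 2 3 29.787701
c6 C N 3 0 32.174395
c6 C N 3 1 30.523311
c6 C N 3 2 29.787701
c6 C N 3 3 29.371069
c6 C N 4 0 31.880558
c6 C N 4 1 30.244553
c6 C N 4 2 29.515662
c6 C N 4 3 29.102835
c6 C O 0 0 27.587135
c6 C O 0 1 26.171454
c6 C O 0 2 25.540724
c6 C O 1 0 26.171454
c6 C O 1 1 24.828421
c6 C O 1 2 24.230058
c6 C O 2 0 25.540724
c6 C O 2 1 24.230058
c6 C O 2 2 23.646115
c6 C O 3 0 25.183493
c6 C O 3 1 23.891159
c6 C O 3 2 23.315384
c6 C O 4 0 24.953502
c6 C O 4 1 23.672971
c6 C O 4 2 23.102454
c6 C Si 0 0 122.374425
c6 C Si 0 1 116.094574
c6 C Si 0 2 113.296703
c6 C Si 0 3 111.712055
c6 C Si 0 4 110.691833
c6 C Si 1 0 116.094574
c6 C Si 1 1 110.136983
c6 C Si 1 2 107.482690
c6 C Si 1 3 105.979361
c6 C Si 1 4 105.011493
c6 C Si 2 0 113.296703
c6 C Si 2 1 107.482690
c6 C Si 2 2 104.892365
c6 C Si 2 3 103.425266
c6 C Si 2 4 102.480724
c6 C Si 3 0 111.712055
c6 C Si 3 1 105.979361
c6 C Si 3 2 103.425266
c6 C Si 3 3 101.978688
c6 C Si 3 4 101.047356
c6 C Si 4 0 110.691833
c6 C Si 4 1 105.011493
c6 C Si 4 2 102.480724
c6 C Si 4 3 101.047356
c6 C Si 4 4 100.124530
c6 C Ar 0 0 56.188344
c6 C Ar 1 0 53.304943
c6 C Ar 2 0 52.020298
c6 C Ar 3 0 51.292706
c6 C Ar 4 0 50.824269
c6 N N 0 0 25.300000
c6 N N 0 1 24.001687
c6 N N 0 2 23.423249
c6 N N 0 3 23.095635
c6 N N 1 0 24.001687
c6 N N 1 1 22.770000
c6 N N 1 2 22.221245
c6 N N 1 3 21.910443
c6 N N 2 0 23.423249
c6 N N 2 1 22.221245
c6 N N 2 2 21.685714
c6 N N 2 3 21.382403
c6 N N 3 0 23.095635
c6 N N 3 1 21.910443
c6 N N 3 2 21.382403
c6 N N 3 3 21.083333
c6 N O 0 0 19.802778
c6 N O 0 1 18.786564
c6 N O 0 2 18.333810
c6 N O 1 0 18.786564
c6 N O 1 1 17.822500
c6 N O 1 2 17.392979
c6 N O 2 0 18.333810
c6 N O 2 1 17.392979
c6 N O 2 2 16.973809
c6 N O 3 0 18.077380
c6 N O 3 1 17.149708
c6 N O 3 2 16.736402
c6 N Si 0 0 87.843611
c6 N Si 0 1 83.335767
c6 N Si 0 2 81.327381
c6 N Si 0 3 80.189879
c6 N Si 0 4 79.457536
c6 N Si 1 0 83.335767
c6 N Si 1 1 79.059250
c6 N Si 1 2 77.153928
c6 N Si 1 3 76.074799
c6 N Si 1 4 75.380037
c6 N Si 2 0 81.327381
c6 N Si 2 1 77.153928
c6 N Si 2 2 75.294524
c6 N Si 2 3 74.241402
c6 N Si 2 4 73.563384
c6 N Si 3 0 80.189879
c6 N Si 3 1 76.074799
c6 N Si 3 2 74.241402
c6 N Si 3 3 73.203009
c6 N Si 3 4 72.534475
c6 N Ar 0 0 40.333485
c6 N Ar 1 0 38.263703
c6 N Ar 2 0 37.341551
c6 N Ar 3 0 36.819266
c6 O O 0 0 15.500000
c6 O O 0 1 14.704591
c6 O O 0 2 14.350212
c6 O O 1 0 14.704591
c6 O O 1 1 13.950000
c6 O O 1 2 13.613806
c6 O O 2 0 14.350212
c6 O O 2 1 13.613806
c6 O O 2 2 13.285714
c6 O Si 0 0 68.756818
c6 O Si 0 1 65.228445
c6 O Si 0 2 63.656444
c6 O Si 0 3 62.766100
c6 O Si 0 4 62.192882
c6 O Si 1 0 65.228445
c6 O Si 1 1 61.881136
c6 O Si 1 2 60.389805
c6 O Si 1 3 59.545151
c6 O Si 1 4 59.001348
c6 O Si 2 0 63.656444
c6 O Si 2 1 60.389805
c6 O Si 2 2 58.934415
c6 O Si 2 3 58.110117
c6 O Si 2 4 57.579420
c6 O Ar 0 0 31.569764
c6 O Ar 1 0 29.949708
c6 O Ar 2 0 29.227922
c6 Si Si 0 0 305.000000
c6 Si Si 0 1 289.348406
c6 Si Si 0 2 282.375130
c6 Si Si 0 3 278.425633
c6 Si Si 0 4 275.882880
c6 Si Si 1 0 289.348406
c6 Si Si 1 1 274.500000
c6 Si Si 1 2 267.884570
c6 Si Si 1 3 264.137748
c6 Si Si 1 4 261.725481
c6 Si Si 2 0 282.375130
c6 Si Si 2 1 267.884570
c6 Si Si 2 2 261.428571
c6 Si Si 2 3 257.772048
c6 Si Si 2 4 255.417916
c6 Si Si 3 0 278.425633
c6 Si Si 3 1 264.137748
c6 Si Si 3 2 257.772048
c6 Si Si 3 3 254.166667
c6 Si Si 3 4 251.845461
c6 Si Si 4 0 275.882880
c6 Si Si 4 1 261.725481
c6 Si Si 4 2 255.417916
c6 Si Si 4 3 251.845461
c6 Si Si 4 4 249.545455
c6 Si Ar 0 0 140.041065
c6 Si Ar 1 0 132.854620
c6 Si Ar 2 0 129.652833
c6 Si Ar 3 0 127.839417
c6 Si Ar 4 0 126.671910
c6 Ar Ar 0 0 64.300000
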