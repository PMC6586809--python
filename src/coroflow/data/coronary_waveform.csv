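phase,w
0.000000,0.61531163
0.015625,0.62700949
0.031250,0.64149138
0.046875,0.65851444
0.062500,0.67744163
0.078125,0.69723619
0.093750,0.71654033
0.109375,0.73384101
0.125000,0.74770148
0.140625,0.75701495
0.156250,0.76122464
0.171875,0.76045733
0.187500,0.75553708
0.203125,0.74787546
0.218750,0.73926562
0.234375,0.73162962
0.250000,0.72677493
0.265625,0.72620682
0.281250,0.73102247
0.296875,0.74188854
0.312500,0.75908434
0.328125,0.78258202
0.343750,0.81213489
0.359375,0.84735183
0.375000,0.88774640
0.390625,0.93275909
0.406250,0.98175850
0.421875,1.03403036
0.437500,1.08876373
0.453125,1.14504153
0.468750,1.20184045
0.484375,1.25804211
0.500000,1.31245577
0.515625,1.36385113
0.531250,1.41099901
0.546875,1.45271703
0.562500,1.48791718
0.578125,1.51565216
0.593750,1.53515732
0.609375,1.54588556
0.625000,1.54753270
0.640625,1.54005185
0.656250,1.52365556
0.671875,1.49880581
0.687500,1.46619237
0.703125,1.42670100
0.718750,1.38137353
0.734375,1.33136228
0.750000,1.27788164
0.765625,1.22215968
0.781250,1.16539230
0.796875,1.10870241
0.812500,1.05310578
0.828125,0.99948500
0.843750,0.94857199
0.859375,0.90093919
0.875000,0.85699888
0.890625,0.81700966
0.906250,0.78108882
0.921875,0.74922913
0.937500,0.72131844
0.953125,0.69716083
0.968750,0.67649771
0.984375,0.65902797
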