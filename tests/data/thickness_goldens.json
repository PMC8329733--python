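{
"seed": 20260929,
"n": 200,
"shape": [
16,
16
],
"spacing": [
1.0,
1.0
],
"masks": [
{
"sum": 218.0,
"max": 2.0
},
{
"sum": 466.34621,
"max": 4.472136
},
{
"sum": 296.769553,
"max": 4.0
},
{
"sum": 515.788889,
"max": 4.0
},
{
"sum": 327.622366,
"max": 2.828427
},
{
"sum": 425.07821,
"max": 4.0
},
{
"sum": 245.39697,
"max": 2.828427
},
{
"sum": 230.083261,
"max": 2.828427
},
{
"sum": 372.818326,
"max": 4.0
},
{
"sum": 795.219083,
"max": 5.656854
},
{
"sum": 524.079493,
"max": 4.472136
},
{
"sum": 128.0,
"max": 2.0
},
{
"sum": 289.965512,
"max": 2.828427
},
{
"sum": 205.59798,
"max": 2.828427
},
{
"sum": 122.0,
"max": 2.0
},
{
"sum": 211.941125,
"max": 2.828427
},
{
"sum": 390.8772,
"max": 4.0
},
{
"sum": 120.0,
"max": 2.0
},
{
"sum": 138.970563,
"max": 2.828427
},
{
"sum": 449.019336,
"max": 4.0
},
{
"sum": 154.0,
"max": 2.0
},
{
"sum": 394.048773,
"max": 4.0
},
{
"sum": 110.0,
"max": 2.0
},
{
"sum": 700.540989,
"max": 4.472136
},
{
"sum": 114.0,
"max": 2.0
},
{
"sum": 232.568542,
"max": 2.828427
},
{
"sum": 162.0,
"max": 2.0
},
{
"sum": 308.936075,
"max": 2.828427
},
{
"sum": 312.627417,
"max": 4.0
},
{
"sum": 637.693083,
"max": 5.656854
},
{
"sum": 475.244733,
"max": 4.0
},
{
"sum": 497.550367,
"max": 4.472136
},
{
"sum": 284.367532,
"max": 2.828427
},
{
"sum": 187.59798,
"max": 2.828427
},
{
"sum": 180.970563,
"max": 2.828427
},
{
"sum": 526.501512,
"max": 4.472136
},
{
"sum": 308.509668,
"max": 2.828427
},
{
"sum": 271.59798,
"max": 2.828427
},
{
"sum": 348.509668,
"max": 4.0
},
{
"sum": 238.710678,
"max": 2.828427
},
{
"sum": 148.0,
"max": 2.0
},
{
"sum": 255.740115,
"max": 2.828427
},
{
"sum": 156.0,
"max": 2.0
},
{
"sum": 146.0,
"max": 2.0
},
{
"sum": 212.970563,
"max": 2.828427
},
{
"sum": 197.79899,
"max": 2.828427
},
{
"sum": 128.0,
"max": 2.0
},
{
"sum": 671.334368,
"max": 4.472136
},
{
"sum": 532.47518,
"max": 4.0
},
{
"sum": 216.769553,
"max": 2.828427
},
{
"sum": 128.0,
"max": 2.0
},
{
"sum": 218.0,
"max": 2.0
},
{
"sum": 574.5779,
"max": 4.472136
},
{
"sum": 328.083261,
"max": 4.0
},
{
"sum": 220.769553,
"max": 2.828427
},
{
"sum": 574.158346,
"max": 4.472136
},
{
"sum": 126.0,
"max": 2.0
},
{
"sum": 575.939842,
"max": 4.472136
},
{
"sum": 362.308658,
"max": 4.0
},
{
"sum": 132.0,
"max": 2.0
},
{
"sum": 449.622366,
"max": 4.0
},
{
"sum": 100.0,
"max": 2.0
},
{
"sum": 196.0,
"max": 2.0
},
{
"sum": 494.405085,
"max": 4.472136
},
{
"sum": 122.0,
"max": 2.0
},
{
"sum": 114.0,
"max": 2.0
},
{
"sum": 511.705627,
"max": 4.0
},
{
"sum": 399.847763,
"max": 4.0
},
{
"sum": 158.0,
"max": 2.0
},
{
"sum": 620.818326,
"max": 4.0
},
{
"sum": 154.0,
"max": 2.0
},
{
"sum": 285.480231,
"max": 2.828427
},
{
"sum": 411.681241,
"max": 4.0
},
{
"sum": 163.79899,
"max": 2.828427
},
{
"sum": 320.793939,
"max": 2.828427
},
{
"sum": 401.220346,
"max": 4.0
},
{
"sum": 270.284271,
"max": 4.0
},
{
"sum": 272.485281,
"max": 4.0
},
{
"sum": 303.137085,
"max": 2.828427
},
{
"sum": 186.142136,
"max": 2.828427
},
{
"sum": 327.882251,
"max": 4.0
},
{
"sum": 172.0,
"max": 2.0
},
{
"sum": 353.849688,
"max": 4.472136
},
{
"sum": 244.568542,
"max": 4.0
},
{
"sum": 238.426407,
"max": 2.828427
},
{
"sum": 188.0,
"max": 2.0
},
{
"sum": 269.740115,
"max": 2.828427
},
{
"sum": 130.0,
"max": 2.0
},
{
"sum": 100.0,
"max": 2.0
},
{
"sum": 561.491513,
"max": 4.472136
},
{
"sum": 343.421356,
"max": 2.828427
},
{
"sum": 126.0,
"max": 2.0
},
{
"sum": 421.803959,
"max": 4.472136
},
{
"sum": 415.965512,
"max": 4.0
},
{
"sum": 290.651804,
"max": 2.828427
},
{
"sum": 483.87215,
"max": 4.0
},
{
"sum": 582.120814,
"max": 4.472136
},
{
"sum": 246.426407,
"max": 2.828427
},
{
"sum": 453.847763,
"max": 4.0
},
{
"sum": 488.014285,
"max": 4.0
},
{
"sum": 398.534055,
"max": 4.0
},
{
"sum": 168.142136,
"max": 2.828427
},
{
"sum": 196.970563,
"max": 2.828427
},
{
"sum": 210.970563,
"max": 2.828427
},
{
"sum": 120.0,
"max": 2.0
},
{
"sum": 317.882251,
"max": 4.0
},
{
"sum": 272.225397,
"max": 2.828427
},
{
"sum": 438.132034,
"max": 4.0
},
{
"sum": 423.587878,
"max": 4.0
},
{
"sum": 174.970563,
"max": 2.828427
},
{
"sum": 166.0,
"max": 2.0
},
{
"sum": 274.970563,
"max": 4.0
},
{
"sum": 106.0,
"max": 2.0
},
{
"sum": 142.0,
"max": 2.0
},
{
"sum": 357.504617,
"max": 2.828427
},
{
"sum": 295.137085,
"max": 2.828427
},
{
"sum": 249.338095,
"max": 2.828427
},
{
"sum": 186.970563,
"max": 2.828427
},
{
"sum": 425.220346,
"max": 4.0
},
{
"sum": 405.906638,
"max": 4.0
},
{
"sum": 285.941125,
"max": 4.0
},
{
"sum": 155.79899,
"max": 2.828427
},
{
"sum": 148.0,
"max": 2.0
},
{
"sum": 160.0,
"max": 2.0
},
{
"sum": 324.509668,
"max": 4.0
},
{
"sum": 300.793939,
"max": 2.828427
},
{
"sum": 138.284271,
"max": 2.828427
},
{
"sum": 704.204095,
"max": 4.472136
},
{
"sum": 410.47518,
"max": 4.0
},
{
"sum": 666.391939,
"max": 4.472136
},
{
"sum": 436.735065,
"max": 4.0
},
{
"sum": 132.0,
"max": 2.0
},
{
"sum": 310.509668,
"max": 2.828427
},
{
"sum": 122.0,
"max": 2.0
},
{
"sum": 269.195959,
"max": 2.828427
},
{
"sum": 140.0,
"max": 2.0
},
{
"sum": 435.102597,
"max": 4.0
},
{
"sum": 189.254834,
"max": 2.828427
},
{
"sum": 380.391919,
"max": 4.0
},
{
"sum": 503.788889,
"max": 4.0
},
{
"sum": 749.460004,
"max": 6.324555
},
{
"sum": 227.254834,
"max": 2.828427
},
{
"sum": 188.0,
"max": 2.0
},
{
"sum": 371.705627,
"max": 2.828427
},
{
"sum": 325.740115,
"max": 4.0
},
{
"sum": 544.467024,
"max": 4.472136
},
{
"sum": 132.0,
"max": 2.0
},
{
"sum": 108.0,
"max": 2.0
},
{
"sum": 567.919824,
"max": 4.472136
},
{
"sum": 128.0,
"max": 2.0
},
{
"sum": 176.970563,
"max": 2.828427
},
{
"sum": 267.195959,
"max": 2.828427
},
{
"sum": 407.122056,
"max": 4.472136
},
{
"sum": 245.941125,
"max": 2.828427
},
{
"sum": 106.0,
"max": 2.0
},
{
"sum": 329.906638,
"max": 2.828427
},
{
"sum": 360.308658,
"max": 4.0
},
{
"sum": 667.38306,
"max": 5.656854
},
{
"sum": 244.284271,
"max": 2.828427
},
{
"sum": 643.450172,
"max": 4.472136
},
{
"sum": 200.911688,
"max": 2.828427
},
{
"sum": 165.455844,
"max": 2.828427
},
{
"sum": 459.290482,
"max": 4.472136
},
{
"sum": 263.681241,
"max": 2.828427
},
{
"sum": 532.07316,
"max": 4.0
},
{
"sum": 104.0,
"max": 2.0
},
{
"sum": 498.934191,
"max": 4.472136
},
{
"sum": 148.0,
"max": 2.0
},
{
"sum": 459.991823,
"max": 4.472136
},
{
"sum": 124.0,
"max": 2.0
},
{
"sum": 130.0,
"max": 2.0
},
{
"sum": 273.59798,
"max": 2.828427
},
{
"sum": 443.893513,
"max": 4.472136
},
{
"sum": 261.195959,
"max": 2.828427
},
{
"sum": 337.338095,
"max": 4.0
},
{
"sum": 713.86097,
"max": 4.472136
},
{
"sum": 460.333044,
"max": 4.0
},
{
"sum": 132.0,
"max": 2.0
},
{
"sum": 702.735126,
"max": 4.472136
},
{
"sum": 138.970563,
"max": 2.828427
},
{
"sum": 166.0,
"max": 2.0
},
{
"sum": 267.254834,
"max": 2.828427
},
{
"sum": 329.421356,
"max": 2.828427
},
{
"sum": 777.290543,
"max": 6.0
},
{
"sum": 172.142136,
"max": 2.828427
},
{
"sum": 88.0,
"max": 2.0
},
{
"sum": 260.568542,
"max": 2.828427
},
{
"sum": 467.895997,
"max": 4.472136
},
{
"sum": 644.1452,
"max": 4.472136
},
{
"sum": 206.911688,
"max": 2.828427
},
{
"sum": 390.450793,
"max": 4.0
},
{
"sum": 515.271044,
"max": 4.472136
},
{
"sum": 265.338095,
"max": 2.828427
},
{
"sum": 390.190909,
"max": 4.0
},
{
"sum": 291.338095,
"max": 2.828427
},
{
"sum": 215.79899,
"max": 2.828427
},
{
"sum": 212.769553,
"max": 2.828427
},
{
"sum": 807.906699,
"max": 6.0
},
{
"sum": 228.970563,
"max": 2.828427
},
{
"sum": 615.948579,
"max": 4.472136
}
]
}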