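{
 "type": "Polygon",
 "coordinates": [
  [
   [
    5096.060532419749,
    6392.388971602861
   ],
   [
    10039.8014876084,
    5898.014876083996
   ],
   [
    10116.685563526906,
    5882.602246810455
   ],
   [
    10189.08547867709,
    5852.486427757801
   ],
   [
    10254.218944922075,
    5808.82475296308
   ],
   [
    10309.582919681328,
    5753.295116102905
   ],
   [
    10353.049796453332,
    5688.031489980433
   ],
   [
    10382.949167540239,
    5615.541919147287
   ],
   [
    10398.132016878943,
    5538.612137157967
   ],
   [
    10398.014876083995,
    5460.1985123916
   ],
   [
    10382.602246810455,
    5383.314436473094
   ],
   [
    10352.4864277578,
    5310.9145213229085
   ],
   [
    10308.82475296308,
    5245.781055077926
   ],
   [
    10253.295116102905,
    5190.417080318672
   ],
   [
    10188.031489980433,
    5146.950203546669
   ],
   [
    10115.541919147287,
    5117.050832459761
   ],
   [
    10038.612137157967,
    5101.8679831210575
   ],
   [
    9960.1985123916,
    5101.985123916004
   ],
   [
    4960.1985123916,
    5601.985123916004
   ],
   [
    4851.443729458359,
    5628.609323645896
   ],
   [
    -148.55627054164148,
    7628.609323645896
   ],
   [
    -218.15653010255193,
    7664.727382010379
   ],
   [
    -279.37315655521263,
    7713.729779061152
   ],
   [
    -329.85362927572777,
    7773.733380160416
   ],
   [
    -367.6580120072232,
    7842.432280568333
   ],
   [
    -391.33350352226955,
    7917.186420069013
   ],
   [
    -399.9702679593122,
    7995.123039004052
   ],
   [
    -393.236399304589,
    8073.2470768151325
   ],
   [
    -371.39067635410373,
    8148.556270541641
   ],
   [
    -335.27261798962104,
    8218.156530102551
   ],
   [
    -286.2702209388477,
    8279.373156555213
   ],
   [
    -226.26661983958388,
    8329.853629275727
   ],
   [
    -157.56771943166703,
    8367.658012007223
   ],
   [
    -82.81357993098628,
    8391.33350352227
   ],
   [
    -4.876960995948582,
    8399.970267959312
   ],
   [
    73.24707681513219,
    8393.23639930459
   ],
   [
    148.55627054164148,
    8371.390676354104
   ],
   [
    5096.060532419749,
    6392.388971602861
   ]
  ]
 ]
}
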