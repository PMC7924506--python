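{
 "type": "Polygon",
 "coordinates": [
  [
   [
    10000.0,
    0.0
   ],
   [
    10000.0,
    3000.0
   ],
   [
    0.0,
    3000.0
   ],
   [
    0.0,
    0.0
   ],
   [
    10000.0,
    0.0
   ]
  ]
 ]
}
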