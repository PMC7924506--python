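{
 "type": "Polygon",
 "coordinates": [
  [
   [
    8000.0,
    8000.0
   ],
   [
    8000.0,
    9500.0
   ],
   [
    6000.0,
    9500.0
   ],
   [
    6000.0,
    8000.0
   ],
   [
    8000.0,
    8000.0
   ]
  ]
 ]
}
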