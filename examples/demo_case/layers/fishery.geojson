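{
 "type": "MultiPolygon",
 "coordinates": [
  [
   [
    [
     4500.0,
     500.0
    ],
    [
     4500.0,
     9500.0
    ],
    [
     500.0,
     9500.0
    ],
    [
     500.0,
     500.0
    ],
    [
     4500.0,
     500.0
    ]
   ]
  ],
  [
   [
    [
     8500.0,
     2500.0
    ],
    [
     8471.177920604845,
     2207.3645169758074
    ],
    [
     8385.81929876693,
     1925.9748514523653
    ],
    [
     8247.204418453817,
     1666.6446504705968
    ],
    [
     8060.660171779821,
     1439.3398282201788
    ],
    [
     7833.355349529404,
     1252.7955815461821
    ],
    [
     7574.025148547635,
     1114.1807012330698
    ],
    [
     7292.635483024193,
     1028.8220793951543
    ],
    [
     7000.0,
     1000.0
    ],
    [
     6707.364516975807,
     1028.8220793951543
    ],
    [
     6425.974851452365,
     1114.1807012330698
    ],
    [
     6166.644650470597,
     1252.795581546182
    ],
    [
     5939.339828220179,
     1439.3398282201786
    ],
    [
     5752.795581546182,
     1666.6446504705968
    ],
    [
     5614.18070123307,
     1925.9748514523653
    ],
    [
     5528.822079395154,
     2207.364516975807
    ],
    [
     5500.0,
     2500.0
    ],
    [
     5528.822079395154,
     2792.6354830241926
    ],
    [
     5614.18070123307,
     3074.0251485476347
    ],
    [
     5752.795581546182,
     3333.3553495294027
    ],
    [
     5939.339828220179,
     3560.660171779821
    ],
    [
     6166.644650470596,
     3747.204418453818
    ],
    [
     6425.974851452364,
     3885.81929876693
    ],
    [
     6707.364516975807,
     3971.1779206048454
    ],
    [
     7000.0,
     4000.0
    ],
    [
     7292.635483024193,
     3971.177920604846
    ],
    [
     7574.025148547635,
     3885.81929876693
    ],
    [
     7833.355349529403,
     3747.204418453818
    ],
    [
     8060.660171779821,
     3560.660171779821
    ],
    [
     8247.204418453817,
     3333.355349529403
    ],
    [
     8385.81929876693,
     3074.0251485476356
    ],
    [
     8471.177920604845,
     2792.635483024193
    ],
    [
     8500.0,
     2500.0
    ]
   ]
  ]
 ]
}
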