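{
  "title": "demo coastal case",
  "version": "1",
  "grid": {
    "extent": [
      0,
      0,
      10000,
      10000
    ],
    "resolution": 500,
    "crs": "EPSG:3035"
  },
  "layers": [
    {
      "name": "fishery",
      "role": "use",
      "file": "layers/fishery.geojson"
    },
    {
      "name": "transport",
      "role": "use",
      "file": "layers/transport.geojson"
    },
    {
      "name": "aquaculture",
      "role": "use",
      "file": "layers/aquaculture.geojson"
    },
    {
      "name": "seagrass",
      "role": "env",
      "file": "layers/seagrass_extent.geojson",
      "expression": "norm(gaussian(seagrass, 1500))"
    },
    {
      "name": "mammals",
      "role": "env",
      "file": "layers/mammal_core.geojson",
      "expression": "norm(gaussian(mammals, 3000))"
    }
  ]
}
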