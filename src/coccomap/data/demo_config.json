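{
  "seed": 0,
  "out_dir": "coccomap_out",
  "simulate": {
    "experiment": "C",
    "species": "C. pelagicus",
    "pixel_size_nm": 50.0,
    "render_spectra": false
  },
  "transects": ["20,84:203,84"]
}
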