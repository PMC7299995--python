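# Synthetic certified calibration standard (bovine-liver-like matrix).
# Mass fractions are invented round numbers used to exercise the
# flux-area calibration chain; they are not NIST certificate values.
element,certified_ppm
Ca,116.0
Fe,184.0
Cu,160.0
Zn,127.0
Sr,100.0
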