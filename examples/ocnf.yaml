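# Experimentally anchored Stark parameters for the o-cyanophenylalanine
# probe in a protein host.
vse:
  nu0: 2236.9
  dmu: 0.2748
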