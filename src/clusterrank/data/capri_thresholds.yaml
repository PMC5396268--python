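# Quality-class threshold table for docked complexes, ordered best first.
# A model gets the first class whose conditions it satisfies:
#   fnat >= fnat_min  AND  (lrmsd <= lrmsd_max  OR  irmsd <= irmsd_max)
# Models satisfying no row are classed "incorrect".
classes:
  - name: high
    fnat_min: 0.5
    lrmsd_max: 1.0
    irmsd_max: 1.0
  - name: medium
    fnat_min: 0.3
    lrmsd_max: 5.0
    irmsd_max: 2.0
  - name: acceptable
    fnat_min: 0.1
    lrmsd_max: 10.0
    irmsd_max: 4.0
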