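# Demo run: two simulated conditions differing only in focus coalescence.
# "dispersed" keeps all truth foci separate; "coalesced" fuses every
# in-nucleus focus pair into one spot at conserved total intensity.  The
# pipeline should report fewer, individually brighter foci in "coalesced"
# at an unchanged per-nucleus total.
simulate:
  field_shape: [420, 420]
  n_z: 12
  n_nuclei: 50
  conditions:
    - name: dispersed
      overrides:
        merge_fraction: 0.0
    - name: coalesced
      overrides:
        merge_fraction: 1.0

bins:
  edges: tertiles
  metric: focus_intensity

compare:
  equal_var: false
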