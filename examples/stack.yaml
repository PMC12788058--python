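# The default sensor: SF11-type prism (constant index), 2 nm chromium
# adhesion layer, 48 nm gold film, aqueous analyte.
incident_angle_deg: 51.2
layers:
  - name: prism
    thickness_nm: null          # semi-infinite
    dispersion: {variant: constant, n: 1.785}
  - name: chromium
    thickness_nm: 2.0
    dispersion: {variant: tabulated, table: cr_nk_synthetic}
  - name: gold
    thickness_nm: 48.0
    dispersion: {variant: tabulated, table: au_nk}
  - name: analyte
    thickness_nm: null
    dispersion: {variant: constant, n: 1.333}
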