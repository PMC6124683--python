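# Default layered optical model of the human calf for reflectance oximetry.
#
# Layer structure: 0.3 mm dermis, 1 mm subdermis (subcutaneous fat), and a
# semi-infinite muscle layer. Optical properties are literature mid-range
# values for skin, subcutaneous fat and skeletal muscle in the 700-900 nm
# window (absorption mu_a and scattering mu_s in mm^-1, Henyey-Greenstein
# anisotropy g, refractive index n). thickness_mm: null marks the
# semi-infinite final layer.
version: calf-v1
n_ambient: 1.0
layers:
  - name: dermis
    thickness_mm: 0.3
    g: 0.9
    n: 1.4
    mu_a: {735: 0.035, 805: 0.030, 850: 0.030}
    mu_s: {735: 22.0, 805: 20.0, 850: 19.0}
  - name: subdermis
    thickness_mm: 1.0
    g: 0.9
    n: 1.4
    mu_a: {735: 0.011, 805: 0.010, 850: 0.011}
    mu_s: {735: 12.5, 805: 12.0, 850: 11.5}
  - name: muscle
    thickness_mm: null
    g: 0.9
    n: 1.4
    mu_a: {735: 0.023, 805: 0.020, 850: 0.022}
    mu_s: {735: 7.0, 805: 6.5, 850: 6.3}
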