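# Candidate magnet catalogue for the two-DoF orientation-sensing build.
# All candidates fit the available pocket (approx. 12 x 3 mm cylindrical
# envelope).  Remanence vectors are in the magnet body frame, mT
# (N42 NdFeB ~ 1300 mT, N45H ~ 1340 mT); "hyp" marks hypothetical
# shape/magnetisation variants, "DI" a diametral in-plane variant.
magnets:
  - name: disc 8x2 axial
    shape: cylinder
    dimensions: [8.0, 2.0]
    br_mT: [0.0, 0.0, 1300.0]
    grade: N42
  - name: disc 8x1 diametral
    shape: cylinder
    dimensions: [8.0, 1.0]
    br_mT: [1300.0, 0.0, 0.0]
    grade: N42
  - name: disc 8x2 diametral (hyp)
    shape: cylinder
    dimensions: [8.0, 2.0]
    br_mT: [1300.0, 0.0, 0.0]
    grade: N42
  - name: rect 6x4x2 axial
    shape: cuboid
    dimensions: [6.0, 4.0, 2.0]
    br_mT: [0.0, 0.0, 1340.0]
    grade: N45H
  - name: rect 2.5x7x2.5 axial
    shape: cuboid
    dimensions: [2.5, 7.0, 2.5]
    br_mT: [0.0, 0.0, 1300.0]
    grade: N42
  - name: rect 2.5x7x2.5 in-plane (DI)
    shape: cuboid
    dimensions: [2.5, 7.0, 2.5]
    br_mT: [1300.0, 0.0, 0.0]
    grade: N42
  - name: rect 10x3x2 axial
    shape: cuboid
    dimensions: [10.0, 3.0, 2.0]
    br_mT: [0.0, 0.0, 1300.0]
    grade: N42
  - name: rect 7x7x2 axial (hyp)
    shape: cuboid
    dimensions: [7.0, 7.0, 2.0]
    br_mT: [0.0, 0.0, 1300.0]
    grade: N42
  - name: rect 7x7x2 in-plane (hyp)
    shape: cuboid
    dimensions: [7.0, 7.0, 2.0]
    br_mT: [1300.0, 0.0, 0.0]
    grade: N42
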