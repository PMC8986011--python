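# Paper-mimicking default scenario: four habitats, strong selection for the
# smallest habitat, avoidance of the largest, order-of-magnitude wet decline.
habitats:
  Cocoa Crop: 59940
  Riparian Forest: 450552
  Star Grass Paddock: 54968
  King Grass Crop: 13245
trap_fraction: 0.6
seed: 42
reps: 200
scenarios:
  - group: larva
    season: dry
    total: 2533
    weights:
      Cocoa Crop: 2.577
      Riparian Forest: 0.3783
      Star Grass Paddock: 1.675
      King Grass Crop: 12.21
  - group: nymph
    season: dry
    total: 4021
    weights:
      Cocoa Crop: 1.926
      Riparian Forest: 0.2539
      Star Grass Paddock: 1.225
      King Grass Crop: 21.25
  - group: female
    season: dry
    total: 94
    weights:
      Cocoa Crop: 1.438
      Riparian Forest: 0.5602
      Star Grass Paddock: 1.904
      King Grass Crop: 10.23
  - group: male
    season: dry
    total: 85
    weights:
      Cocoa Crop: 0.6815
      Riparian Forest: 0.3627
      Star Grass Paddock: 0.3716
      King Grass Crop: 26.73
  - group: larva
    season: wet
    total: 80
    weights:
      Cocoa Crop: 0.01
      Riparian Forest: 0.01
      Star Grass Paddock: 8.817
      King Grass Crop: 7.1
  - group: nymph
    season: wet
    total: 22
    weights:
      Cocoa Crop: 0.01
      Riparian Forest: 0.4671
      Star Grass Paddock: 4.785
      King Grass Crop: 7.944
  - group: female
    season: wet
    total: 77
    weights:
      Cocoa Crop: 1.755
      Riparian Forest: 0.367
      Star Grass Paddock: 1.641
      King Grass Crop: 16.46
  - group: male
    season: wet
    total: 87
    weights:
      Cocoa Crop: 2.552
      Riparian Forest: 0.3986
      Star Grass Paddock: 1.21
      King Grass Crop: 13.56
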