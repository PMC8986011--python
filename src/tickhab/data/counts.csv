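group,habitat,season,method,count
larva,Star Grass Paddock,dry,trap,205
nymph,Star Grass Paddock,dry,trap,431
female,Star Grass Paddock,dry,trap,17
male,Star Grass Paddock,dry,trap,3
larva,King Grass Crop,dry,trap,212
nymph,King Grass Crop,dry,trap,1882
female,King Grass Crop,dry,trap,22
male,King Grass Crop,dry,trap,52
larva,Riparian Forest,dry,trap,532
nymph,Riparian Forest,dry,trap,757
female,Riparian Forest,dry,trap,39
male,Riparian Forest,dry,trap,24
larva,Cocoa Crop,dry,trap,61
nymph,Cocoa Crop,dry,trap,729
female,Cocoa Crop,dry,trap,10
male,Cocoa Crop,dry,trap,5
larva,Star Grass Paddock,wet,trap,0
nymph,Star Grass Paddock,wet,trap,10
female,Star Grass Paddock,wet,trap,12
male,Star Grass Paddock,wet,trap,10
larva,King Grass Crop,wet,trap,0
nymph,King Grass Crop,wet,trap,4
female,King Grass Crop,wet,trap,28
male,King Grass Crop,wet,trap,27
larva,Riparian Forest,wet,trap,0
nymph,Riparian Forest,wet,trap,5
female,Riparian Forest,wet,trap,18
male,Riparian Forest,wet,trap,26
larva,Cocoa Crop,wet,trap,0
nymph,Cocoa Crop,wet,trap,0
female,Cocoa Crop,wet,trap,13
male,Cocoa Crop,wet,trap,22
larva,Star Grass Paddock,dry,transect,198
nymph,Star Grass Paddock,dry,transect,37
female,Star Grass Paddock,dry,transect,0
male,Star Grass Paddock,dry,transect,0
larva,King Grass Crop,dry,transect,496
nymph,King Grass Crop,dry,transect,74
female,King Grass Crop,dry,transect,0
male,King Grass Crop,dry,transect,0
larva,Riparian Forest,dry,transect,214
nymph,Riparian Forest,dry,transect,38
female,Riparian Forest,dry,transect,2
male,Riparian Forest,dry,transect,0
larva,Cocoa Crop,dry,transect,615
nymph,Cocoa Crop,dry,transect,73
female,Cocoa Crop,dry,transect,4
male,Cocoa Crop,dry,transect,1
larva,Star Grass Paddock,wet,transect,67
nymph,Star Grass Paddock,wet,transect,0
female,Star Grass Paddock,wet,transect,0
male,Star Grass Paddock,wet,transect,0
larva,King Grass Crop,wet,transect,13
nymph,King Grass Crop,wet,transect,0
female,King Grass Crop,wet,transect,1
male,King Grass Crop,wet,transect,0
larva,Riparian Forest,wet,transect,0
nymph,Riparian Forest,wet,transect,3
female,Riparian Forest,wet,transect,4
male,Riparian Forest,wet,transect,1
larva,Cocoa Crop,wet,transect,0
nymph,Cocoa Crop,wet,transect,0
female,Cocoa Crop,wet,transect,1
male,Cocoa Crop,wet,transect,1
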