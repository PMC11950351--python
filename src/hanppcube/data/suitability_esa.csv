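# Correspondence between ESA-CCI-style land-cover classes and land-use types:
# per class, the share (%) of its area available to each land-use column.
# Columns: builtup; cropland suitability 1-3; grazing suitability 1-3;
# closed forest coniferous / non-coniferous; open wooded land con / ncon.
# Cropland and grazing suitability classes 1 and 2 deliberately overlap the
# same source classes; overlapping claims are resolved by the sequential
# allocation order, not here.
# Rows flagged AMBIGUOUS: the published column alignment of these shares is
# uncertain in our transcription; the engine treats this file as opaque
# configuration so corrections never require code changes.
code,name,builtup,crop1,crop2,crop3,graz1,graz2,graz3,forest_con,forest_ncon,owl_con,owl_ncon
10,"Cropland, rainfed",0,95,0,0,100,0,0,0,0,0,0
11,"Herbaceous cover",0,95,0,0,100,0,0,0,0,0,0
12,"Tree or shrub cover",0,95,0,0,100,0,0,0,0,0,0
20,"Cropland, irrigated or post-flooding",0,95,0,0,100,0,0,0,0,0,0
30,"Mosaic cropland (>50%) / natural vegetation (<50%)",0,0,60,0,0,60,40,0,0,8,32
40,"Mosaic natural vegetation (>50%) / cropland (<50%)",0,0,40,0,0,40,60,0,0,13,47
50,"Tree cover, broadleaved, evergreen, closed to open (>15%)",0,0,0,0,0,0,0,0,100,0,0
60,"Tree cover, broadleaved, deciduous, closed to open (>15%)",0,0,0,0,0,0,0,0,100,0,0
61,"Tree cover, broadleaved, deciduous, closed (>40%)",0,0,0,0,0,0,0,0,100,0,0
62,"Tree cover, broadleaved, deciduous, open (15-40%)",0,0,0,35,0,0,100,0,0,0,55
70,"Tree cover, needleleaved, evergreen, closed to open (>15%)",0,0,0,0,0,0,0,100,0,0,0
71,"Tree cover, needleleaved, evergreen, closed (>40%)",0,0,0,0,0,0,0,100,0,0,0
72,"Tree cover, needleleaved, evergreen, open (15-40%)",0,0,0,30,0,0,100,0,0,35,5
80,"Tree cover, needleleaved, deciduous, closed to open (>15%)",0,0,0,0,0,0,0,100,0,0,0
81,"Tree cover, needleleaved, deciduous, closed (>40%)",0,0,0,0,0,0,0,100,0,0,0
82,"Tree cover, needleleaved, deciduous, open (15-40%)",0,0,0,30,0,0,100,0,0,35,5
90,"Tree cover, mixed leaf type (broadleaved and needleleaved)",0,0,0,0,0,0,0,50,50,0,0
100,"Mosaic tree and shrub (>50%) / herbaceous cover (<50%)",0,0,0,40,0,0,100,0,0,15,45
110,"Mosaic herbaceous cover (>50%) / tree and shrub (<50%)",0,0,0,60,0,0,100,0,0,10,30
120,"Shrubland",0,0,95,0,0,100,0,0,0,20,40
121,"Evergreen shrubland",0,0,95,0,0,100,0,0,0,30,30
122,"Deciduous shrubland",0,0,95,0,0,100,0,0,0,0,60
130,"Grassland",0,0,95,0,0,100,0,0,0,0,0
140,"Lichens and mosses",0,0,0,0,0,0,100,0,0,0,0
150,"Sparse vegetation (tree, shrub, herbaceous cover) (<15%)",0,0,0,95,0,0,100,0,0,0,0
151,"Sparse tree (<15%)",0,0,0,95,0,0,100,0,0,0,28
152,"Sparse shrub (<15%)",0,0,0,95,0,0,100,0,0,0,28
153,"Sparse herbaceous cover (<15%)",0,0,0,95,0,0,100,0,0,0,0
160,"Tree cover, flooded, fresh or brakish water",0,0,0,0,0,0,0,50,50,0,0
170,"Tree cover, flooded, saline water",0,0,0,0,0,0,0,0,100,0,0
180,"Shrub or herbaceous cover, flooded",0,0,0,0,0,0,100,0,0,0,0
190,"Urban areas",100,0,0,0,0,0,0,0,0,0,0
200,"Bare areas",0,0,0,0,0,0,0,0,0,0,0
210,"Water bodies",0,0,0,0,0,0,0,0,0,0,0
220,"Permanent snow and ice",0,0,0,0,0,0,0,0,0,0,0
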