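# Default reclassification of the 37 ESA-CCI land-cover codes to the
# 8 thematic classes used in the detour analysis.  This grouping is the
# package's own best-guess ecological aggregation (sparse vegetation
# variants merged into "Open natural ecosystem", flooded forests kept
# with "Forest", all bare-area subtypes merged); edit freely — the
# loader validates only that every code you sample is mapped.

[mapping]
10 = "Cropland"                      # rainfed cropland
11 = "Cropland"                      # rainfed, herbaceous cover
12 = "Cropland"                      # rainfed, tree or shrub cover
20 = "Cropland"                      # irrigated cropland
30 = "Cropland mosaic"               # mosaic cropland / natural veg.
40 = "Cropland mosaic"               # mosaic natural veg. / cropland
50 = "Forest"                        # broadleaved evergreen
60 = "Forest"                        # broadleaved deciduous
61 = "Forest"                        # broadleaved deciduous, closed
62 = "Forest"                        # broadleaved deciduous, open
70 = "Forest"                        # needleleaved evergreen
71 = "Forest"                        # needleleaved evergreen, closed
72 = "Forest"                        # needleleaved evergreen, open
80 = "Forest"                        # needleleaved deciduous
81 = "Forest"                        # needleleaved deciduous, closed
82 = "Forest"                        # needleleaved deciduous, open
90 = "Forest"                        # mixed leaf type
100 = "Forest"                       # mosaic tree and shrub / herbaceous
110 = "Open natural ecosystem"       # mosaic herbaceous / tree and shrub
120 = "Open natural ecosystem"       # shrubland
121 = "Open natural ecosystem"       # evergreen shrubland
122 = "Open natural ecosystem"       # deciduous shrubland
130 = "Open natural ecosystem"       # grassland
140 = "Open natural ecosystem"       # lichens and mosses
150 = "Open natural ecosystem"       # sparse vegetation
151 = "Open natural ecosystem"       # sparse tree
152 = "Open natural ecosystem"       # sparse shrub
153 = "Open natural ecosystem"       # sparse herbaceous
160 = "Forest"                       # tree cover, flooded, fresh water
170 = "Forest"                       # tree cover, flooded, saline water
180 = "Open natural ecosystem"       # shrub/herbaceous, flooded
190 = "Urban areas"
200 = "Bare areas"
201 = "Bare areas"                   # consolidated
202 = "Bare areas"                   # unconsolidated
210 = "Water body"
220 = "Permanent snow and ice"
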