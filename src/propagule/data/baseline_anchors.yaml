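# Editable anchor fixture for the baseline two-deme demography.
#
# Effective-size anchors on a 23-point log grid between 3 ka and 2 Ma
# (times in years before present, sizes in individuals).  The island
# trajectory follows the inferred island history between the present and
# 200 ka (long-term plateau near 30 K with a glacial trough near 10 K
# between 15 and 40 ka) and is spliced onto the mainland (ancestral)
# trajectory for times more ancient than 200 ka.  These are round-number
# approximations of the published point estimates, which are available
# only as supplementary material; replace them with your own values to
# fit other systems.
island:
  - [3000.0, 30000.0]
  - [4031.63, 30000.0]
  - [5418.02, 30000.0]
  - [7281.15, 30000.0]
  - [9784.96, 30000.0]
  - [13149.8, 30000.0]
  - [17671.7, 10000.0]
  - [23748.6, 10000.0]
  - [31915.2, 10000.0]
  - [42890.1, 30000.0]
  - [57639.0, 30000.0]
  - [77459.7, 30000.0]
  - [104096.0, 30000.0]
  - [139893.0, 30000.0]
  - [187998.0, 30000.0]
  - [252647.0, 50000.0]
  - [339526.0, 50000.0]
  - [456281.0, 50000.0]
  - [613186.0, 50000.0]
  - [824046.0, 50000.0]
  - [1107420.0, 50000.0]
  - [1488230.0, 50000.0]
  - [2000000.0, 50000.0]
mainland:
  - [3000.0, 45000.0]
  - [4031.63, 45000.0]
  - [5418.02, 45000.0]
  - [7281.15, 45000.0]
  - [9784.96, 45000.0]
  - [13149.8, 45000.0]
  - [17671.7, 45000.0]
  - [23748.6, 45000.0]
  - [31915.2, 45000.0]
  - [42890.1, 70000.0]
  - [57639.0, 50000.0]
  - [77459.7, 50000.0]
  - [104096.0, 50000.0]
  - [139893.0, 50000.0]
  - [187998.0, 50000.0]
  - [252647.0, 50000.0]
  - [339526.0, 50000.0]
  - [456281.0, 50000.0]
  - [613186.0, 50000.0]
  - [824046.0, 50000.0]
  - [1107420.0, 50000.0]
  - [1488230.0, 50000.0]
  - [2000000.0, 50000.0]
split_time: 85400.0
generation_time: 1.0
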