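{
  "hematopoietic_cells": [
    "promyelocyte",
    "myeloblast",
    "lymphoblast",
    "monocyte",
    "B-lymphocyte",
    "myelo"
  ],
  "max_site_depth": 5
}
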