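{
  "96-well": {
    "diameter_cm": 0.63,
    "wall_height_cm": 1.115,
    "medium_volume_ml": 0.1,
    "seeding_cells": 2500
  },
  "24-well": {
    "diameter_cm": 1.557,
    "wall_height_cm": 1.798,
    "medium_volume_ml": 0.5,
    "seeding_cells": 12500
  },
  "12-well": {
    "diameter_cm": 2.15,
    "wall_height_cm": 1.7,
    "medium_volume_ml": 1.0,
    "seeding_cells": 25000
  },
  "3.5cm-dish": {
    "diameter_cm": 3.36,
    "wall_height_cm": 1.18,
    "medium_volume_ml": 2.0,
    "seeding_cells": 50000
  }
}
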