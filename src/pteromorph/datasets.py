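"""Published study metadata for the flying-squirrel cranial dataset.

The tribe Pteromyini comprises 52 extant species in 14 genera; the cranial
study sampled 35 of them (151 museum specimens photographed in ventral
view).  This module ships the per-species sampling table — specimen counts,
diet category and Walter-biome occupancy — which drives the disparity
analyses and the richness-conditioned null model.

Diet categories: Folivore_1 (leaves/sprouts, no nuts or hard seeds),
Folivore_2 (very abrasive leaves such as conifer needles), Frugivore
(flesh fruit only), Nucivore (hard seeds/nuts, no leaves), Generalist
(leaves plus hard seeds/nuts), NoInfo (diet unknown).

Biomes (Walter classification): I evergreen equatorial rainforest,
II tropical deciduous woodland, II/III savanna, V temperate evergreen
forest, VI broad-leaf deciduous forest, VIII taiga.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .io import validate_metadata

__all__ = [
    "TRIBE_N_SPECIES",
    "TROPICAL_BIOMES",
    "TEMPERATE_BIOMES",
    "pteromyini_metadata",
]

#: Extant species in the tribe Pteromyini.
TRIBE_N_SPECIES = 52

TROPICAL_BIOMES = ("I", "II", "II/III")
TEMPERATE_BIOMES = ("V", "VI", "VIII")

_SPECIES_TABLE = """\
species,N,diet,I,II,II/III,V,VI,VIII
Aeretes melanopterus,2,NoInfo,0,0,0,0,0,1
Aeromys tephromelas,4,Nucivore,1,0,0,0,0,0
Aeromys thomasi,1,Frugivore,1,0,0,0,0,0
Belomys pearsonii,2,Folivore_1,1,1,0,1,1,0
Biswamoyopterus laoensis,1,NoInfo,0,1,0,0,0,0
Eoglaucomys fimbriatus,8,Nucivore,0,0,1,1,0,1
Eupetaurus cinereus,1,Folivore_2,0,0,0,0,0,1
Glaucomys sabrinus,10,Nucivore,0,0,0,0,1,1
Hylopetes alboniger,7,Frugivore,1,1,0,1,0,1
Hylopetes bartelsi,1,NoInfo,1,0,0,0,0,0
Hylopetes nigripes,4,NoInfo,0,1,0,0,0,0
Hylopetes phayrei,6,Frugivore,1,1,0,0,0,0
Hylopetes platyurus,7,Generalist,1,0,0,0,0,0
Hylopetes sagitta,8,NoInfo,1,1,0,0,0,0
Hylopetes spadiceus,10,NoInfo,1,1,0,0,0,0
Iomys horsfieldii,1,Nucivore,1,0,0,0,0,0
Iomys sipora,1,NoInfo,1,0,0,0,0,0
Petaurillus kinlochii,4,NoInfo,1,0,0,0,0,0
Petaurista albiventer,1,Generalist,1,1,0,1,0,0
Petaurista alborufus,5,Generalist,1,1,0,1,1,0
Petaurista elegans,3,Generalist,1,1,0,1,0,1
Petaurista lena,3,Folivore_1,1,1,0,1,0,1
Petaurista leucogenys,6,Generalist,0,0,0,1,1,0
Petaurista petaurista,10,Folivore_1,1,1,0,1,0,1
Petaurista philippensis,5,Folivore_1,1,1,1,1,1,0
Petaurista yunanensis,5,NoInfo,1,1,0,1,1,1
Petinomys crinitus,3,NoInfo,1,1,0,0,0,0
Petinomys fuscocapillus,3,Generalist,1,1,0,0,0,0
Petinomys hageni,2,NoInfo,1,0,0,0,0,0
Petinomys lugens,4,NoInfo,1,0,0,0,0,0
Petinomys setosus,4,Nucivore,1,1,0,0,0,0
Petinomys vordermanni,6,Nucivore,1,0,0,0,0,0
Pteromys volans,6,Generalist,0,0,0,1,1,1
Pteromyscus pulverulentus,5,Generalist,1,0,0,1,0,0
Trogopterus xanthipes,2,Folivore_2,0,0,0,1,1,1
"""


def pteromyini_metadata() -> pd.DataFrame:
    """The sampled-species table: N specimens, diet, biome occupancy."""
    return validate_metadata(pd.read_csv(StringIO(_SPECIES_TABLE)))
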