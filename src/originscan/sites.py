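"""Candidate origin sites used in comparisons.

Coordinates are approximate site locations compiled from the archaeological
literature (the analyses are insensitive to errors of a few tens of km at a
500-km kernel scale); override them freely when better coordinates are
available.

- Dadiwan: early Neolithic site, Qin'an County, Gansu, western Loess Plateau.
- Xinglonggou: early Neolithic site near Chifeng, Inner Mongolia.
- Sokol'tsy: site on the Southern Bug river, Ukraine.
"""

from .geo import GeoPoint

DADIWAN = GeoPoint(35.01, 105.60)
XINGLONGGOU = GeoPoint(42.33, 119.25)
SOKOLTSY = GeoPoint(48.70, 29.90)

SITE_COORDINATES = {
    "Dadiwan": DADIWAN,
    "Xinglonggou": XINGLONGGOU,
    "Sokol'tsy": SOKOLTSY,
}
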