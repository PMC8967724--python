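"""Reference tables for the vagal interoceptive system.

Organ positions are mean rostro-caudal distances from the nodose ganglia,
normalised to body length (neck to rectum), so they live in [0, 1].
Tissue-layer indices order layers from the organ surface inward:
mucosa/inner epithelium (0), muscle (1), connective tissue (2).
"""

from __future__ import annotations

#: Normalised rostro-caudal position of each visceral organ (fraction of
#: body length from the nodose ganglia; measured in adult mice).
ORGAN_POSITIONS: dict[str, float] = {
    "lung": 0.241,
    "heart": 0.280,
    "oesophagus": 0.228,
    "stomach": 0.469,
    "duodenum": 0.567,
    "colon": 0.589,
    "pancreas": 0.545,
}

#: Index score per tissue layer, ordered outer surface -> lumen.
LAYER_INDEX: dict[str, int] = {
    "mucosa": 0,
    "muscle": 1,
    "connective": 2,
}

#: Vagal afferent ending types in the gut wall, in canonical order.
#: ME = mucosal ending, pIMA/cIMA = parallel/circular intramuscular array,
#: IGLE = intraganglionic laminar ending (counted, not area-measured).
ENDING_TYPES: tuple[str, ...] = ("ME", "pIMA", "cIMA", "IGLE")

#: Stomach regions quantified for dual-barcode enrichment.
STOMACH_REGIONS: tuple[int, ...] = (4, 6, 7, 8)
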