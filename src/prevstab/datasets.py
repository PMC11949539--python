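"""Packaged demonstration data.

The coral demo is a SYNTHETIC stand-in for a Caribbean coral / symbiont
survey: generated presence/absence records, not field observations. Its
layout mirrors a real survey design — five coral host taxa (one of them
surveyed at two depths), six symbiont species, eight scored host–symbiont
pairs, and unscored colonies appearing as missing cells.
"""

from __future__ import annotations

from .io import make_fixture_table
from .types import OccurrenceTable

__all__ = ["coral_demo", "CORAL_DEMO_SPEC"]

# (group, symbiont, scored colonies, presences). The Millepora complanata
# trio is sized so the observed prevalences round to 21.1%, 19.2% and
# 23.8% (20/95, 20/104, 24/101); unequal scored counts within the group
# exercise the missing-data path. The Acropora palmata fanworm is set to a
# mid-range prevalence, the regime that needs the largest sampling effort,
# so 35 colonies are expected to be insufficient for it.
CORAL_DEMO_SPEC = [
    ("Acropora palmata", "Domecia acanthophora", 35, 30),
    ("Acropora palmata", "Spirobranchus polycerus", 35, 17),
    ("Agaricia agaricites", "Opecarcinus hypostegus", 120, 78),
    ("Agaricia lamarcki", "Opecarcinus hypostegus", 80, 24),
    ("Millepora complanata", "Megabalanus stultus", 101, 24),
    ("Millepora complanata", "Domecia acanthophora", 104, 20),
    ("Millepora complanata", "Acanthemblemaria spinosa", 95, 20),
    ("Orbicella faveolata (6 m)", "Troglocarcinus corallicola", 130, 52),
    ("Orbicella faveolata (15 m)", "Troglocarcinus corallicola", 117, 35),
]


def coral_demo(seed: int = 0) -> OccurrenceTable:
    """Synthetic coral-dwelling-fauna survey table (see module docstring).

    Deterministic given ``seed``; per-pair presence totals are exact by
    construction, only the row placement of 1s/0s/missing is shuffled.
    """
    return make_fixture_table(CORAL_DEMO_SPEC, seed=seed)
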