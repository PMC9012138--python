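"""Small built-in reference tables.

Only the published tissue-PO2 compilation is shipped; everything else the
pipeline consumes is either user-supplied CSV or generated by
:mod:`oxycap.synthetic_data`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["tissue_po2_reference"]

# Published averages of tissue oxygen tension (torr) measured in the
# undisturbed awake cerebral cortex, one row per study.
_TISSUE_PO2 = [
    ("mouse", 35.0),
    ("mouse", 33.0),
    ("mouse", 25.0),
    ("mouse", 22.0),
    ("rat", 37.0),
    ("rat", 26.7),
    ("rat", 29.0),
    ("rat", 34.0),
    ("rat", 25.0),
    ("human", 23.1),
    ("human", 25.5),
    ("human", 26.9),
    ("human", 29.0),
    ("human", 33.0),
]


def tissue_po2_reference() -> pd.DataFrame:
    """Literature tissue-PO2 averages by species.

    Returns a frame with columns ``species`` and ``po2t`` (torr), one row
    per published study, for mouse, rat and human cortex in the
    undisturbed awake state.
    """
    return pd.DataFrame(_TISSUE_PO2, columns=["species", "po2t"])
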