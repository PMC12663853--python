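"""Canonical atlas tissue set.

The atlas covers 33 tissue labels: 31 assayed in both sexes plus two
sex-specific reproductive organs (testes in males, fallopian tubes in
females), so each animal contributes 32 tissues.
"""

from __future__ import annotations

CROSS_SEX_TISSUES: tuple[str, ...] = (
    "BAT",
    "gWAT",
    "iWAT",
    "Cerebellum",
    "Cortex",
    "Hippocampus",
    "Hypothalamus",
    "Eye",
    "Cecum",
    "Distal colon",
    "Proximal colon",
    "Duodenum",
    "Ileum",
    "Jejunum",
    "Heart atrium",
    "Heart ventricle",
    "Kidney cortex",
    "Kidney medulla",
    "Liver",
    "Lung",
    "Pancreas",
    "Diaphragm",
    "Gastrocnemius",
    "Hamstring",
    "Plantaris",
    "Quadriceps",
    "Soleus",
    "Tongue",
    "Skin",
    "Spleen",
    "Stomach",
)

#: Reproductive tissues present in only one sex; excluded from all
#: cross-sex comparisons.
SEX_SPECIFIC_TISSUES: dict[str, str] = {
    "Testes": "male",
    "Fallopian tubes": "female",
}

ALL_TISSUES: tuple[str, ...] = CROSS_SEX_TISSUES + tuple(SEX_SPECIFIC_TISSUES)


def tissues_for_sex(sex: str) -> tuple[str, ...]:
    """Tissues collectable from an animal of the given sex (32 per animal)."""
    return CROSS_SEX_TISSUES + tuple(
        t for t, s in SEX_SPECIFIC_TISSUES.items() if s == sex
    )
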