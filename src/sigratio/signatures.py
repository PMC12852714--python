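"""Built-in gene-signature registry.

The lists are transcribed verbatim from the literature: a 10-gene
high-risk signature (expected to correlate positively with tumor-cell
genes), a 10-gene low-risk signature (expected negative correlation), and
12-gene M1 (anti-tumoral) and M2 (pro-tumoral) tumor-associated
macrophage/microglia profiles drawn from CIBERSORT expression profiles,
plus the marker genes used in the tier tables (proliferation, MB-subgroup
drivers, CD24/Siglec-10 axis, microglia and macrophage markers).

Two symbols are kept exactly as printed even though they are not standard
HGNC symbols ("ITGB" has no unambiguous gene; "ZPF3" is plausibly ZNF3):
they will simply register as missing on real platforms, which the
denominator-adjustment rules account for.
"""

from __future__ import annotations

from .datatypes import GeneSignature
from .errors import ValidationError

__all__ = ["builtin_signatures", "get_signature", "HIGH_RISK", "LOW_RISK", "M1", "M2", "MARKERS"]

HIGH_RISK = GeneSignature(
    name="high_risk",
    genes=(
        "FOXM1", "NEK2", "CCT2", "ACTL6A", "CCND2",
        "ABL1", "SYNCRIP", "ITGB", "ENAH", "UMPS",
    ),
    role="high_risk",
)

LOW_RISK = GeneSignature(
    name="low_risk",
    genes=(
        "ADAM22", "AEBP1", "DHRS2", "RAC3", "SHANK1",
        "CYB5D2", "IL27RA", "DNAH2", "ZPF3", "NRXN2",
    ),
    role="low_risk",
)

M1 = GeneSignature(
    name="M1",
    genes=(
        "APOL3", "CCL19", "CCL5", "CCR7", "CD38", "CD40",
        "CXCL10", "CXCL9", "EBI3", "IDO1", "LAMP3", "TNFAIP6",
    ),
    role="M1",
)

M2 = GeneSignature(
    name="M2",
    genes=(
        "AIF1", "CCL13", "CCL18", "CD180", "CD209", "CD4",
        "CLEC4A", "CLEC10A", "MS4A6A", "NPL", "SLC15A3", "TREM2",
    ),
    role="M2",
)

MARKERS = GeneSignature(
    name="markers",
    genes=(
        "MKI67", "CTNNB1", "SMO", "MYC", "CDK6", "CD24", "SIGLEC10",
        "TREM2", "CD163", "ITGA4", "P2RY12", "TMEM119", "AIF1", "PTPRC",
    ),
    role="marker",
)


def builtin_signatures() -> list[GeneSignature]:
    """All built-in signatures, in registry order."""
    return [HIGH_RISK, LOW_RISK, M1, M2, MARKERS]


def get_signature(name: str) -> GeneSignature:
    """Look up a built-in signature by name (case-insensitive)."""
    for sig in builtin_signatures():
        if sig.name.lower() == name.lower():
            return sig
    known = [s.name for s in builtin_signatures()]
    raise ValidationError(f"unknown signature {name!r}; built-ins: {known}")
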