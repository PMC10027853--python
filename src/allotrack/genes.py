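"""TCR gene-name normalization across platform dialects.

Adaptive immunoSEQ exports spell beta-chain genes like ``TCRBV05-01*01``
while 10x / IMGT use ``TRBV5-1``.  Matching clonotypes across platforms
requires one canonical spelling; this module converts both dialects to the
IMGT form with the allele suffix stripped.

The conversion is rule-based (prefix substitution, de-zero-padding) with a
packaged exception table (``data/adaptive_imgt_trb.tsv``) for names the rule
cannot derive, such as orphons.  IMGT single-member families (e.g. TRBV28)
drop the ``-01`` member that Adaptive appends; families whose IMGT names
genuinely carry a member index (e.g. TRBV5-1, all J genes) keep it.
"""

from __future__ import annotations

import csv
import functools
import re
from importlib import resources

# IMGT TRB V families whose gene names include a member index.
_MULTI_MEMBER_V_FAMILIES = {
    "TRBV": {3, 4, 5, 6, 7, 10, 11, 12, 20, 21, 23, 24, 25, 26, 29},
    "TRAV": {1, 8, 12, 13, 14, 23, 29, 36, 38},
}

_PREFIX_MAP = {
    "TCRBV": "TRBV", "TCRBJ": "TRBJ", "TCRBD": "TRBD",
    "TCRAV": "TRAV", "TCRAJ": "TRAJ",
    "TCRGV": "TRGV", "TCRGJ": "TRGJ",
    "TCRDV": "TRDV", "TCRDJ": "TRDJ", "TCRDD": "TRDD",
}

_NAME_RE = re.compile(
    r"^(?P<prefix>TCR[ABGD][VDJ]|TR[ABGD][VDJ])"
    r"(?P<family>\d+)"
    r"(?:-(?P<member>\d+))?$"
)


@functools.cache
def _exception_table() -> dict[str, str]:
    text = resources.files("allotrack.data").joinpath("adaptive_imgt_trb.tsv").read_text()
    rows = csv.DictReader(text.splitlines(), delimiter="\t")
    return {r["adaptive"]: r["imgt"] for r in rows}


def strip_allele(name: str) -> str:
    """Remove an IMGT allele suffix: ``TRBV5-1*01`` -> ``TRBV5-1``."""
    return name.split("*", 1)[0].strip()


def normalize_gene(name: str) -> str:
    """Canonical IMGT spelling of a V/D/J gene name, allele stripped.

    Accepts IMGT (``TRBV5-1*01``) and Adaptive (``TCRBV05-01*02``)
    dialects.  Ambiguous Adaptive calls joined by ``/`` are normalized
    part-wise.  Names that match neither dialect (including empty /
    ``unresolved``) are returned allele-stripped but otherwise unchanged.
    """
    name = strip_allele(name)
    if not name:
        return ""
    if "/" in name and name not in _exception_table():
        parts = name.split("/")
        # later parts of an ambiguous call ("TCRBV12-03/12-04") omit the prefix
        prefix_m = re.match(r"^(TCR[ABGD][VDJ]|TR[ABGD][VDJ])", parts[0])
        prefix = prefix_m.group(1) if prefix_m else ""
        fixed = [parts[0]] + [
            p if re.match(r"^T", p) else prefix + p for p in parts[1:]
        ]
        return "/".join(normalize_gene(p) for p in fixed)
    exc = _exception_table()
    if name in exc:
        return exc[name]
    m = _NAME_RE.match(name)
    if m is None:
        return name
    prefix = _PREFIX_MAP.get(m.group("prefix"), m.group("prefix"))
    family = int(m.group("family"))
    member = m.group("member")
    segment = prefix[:4]  # e.g. TRBV
    if member is None:
        return f"{prefix}{family}"
    member_i = int(member)
    multi = _MULTI_MEMBER_V_FAMILIES.get(segment, set())
    if prefix.endswith("V") and member_i == 1 and family not in multi:
        # Adaptive appends -01 to single-member families; IMGT does not.
        return f"{prefix}{family}"
    return f"{prefix}{family}-{member_i}"


def is_vdj_gene(symbol: str) -> bool:
    """True for TR[ABGD][VDJ]-prefixed gene symbols (used to exclude
    clonotype-defining genes from expression feature selection)."""
    return bool(re.match(r"^TR[ABGD][VDJ]", symbol))
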