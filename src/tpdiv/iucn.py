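"""IUCN Red List category vocabulary used throughout the package.

The category set is closed: CR (critically endangered), EN (endangered),
VU (vulnerable), NT (near threatened), LC (least concern), DD (data
deficient) and NE (not evaluated). EX/EW and other codes are rejected at
read time rather than silently remapped.
"""

from __future__ import annotations

IUCN_CATEGORIES: tuple[str, ...] = ("CR", "EN", "VU", "NT", "LC", "DD", "NE")

#: Categories counted as "threatened or near threatened" when tilting the
#: synthetic status generator toward one end of trait space. CR-EN-VU is the
#: formal "threatened" block; NT is included because the most severe
#: deterministic extinction scenario short of -DD removes it as well.
THREAT_TILTED: tuple[str, ...] = ("CR", "EN", "VU", "NT")

#: Species with any status except NE count as assessed; they form the
#: baseline pool for extinction scenarios.
ASSESSED: tuple[str, ...] = ("CR", "EN", "VU", "NT", "LC", "DD")
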