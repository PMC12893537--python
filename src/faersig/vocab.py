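"""Vocabulary (PT -> SOC) and drug dictionaries.

MedDRA itself is licensed and is not shipped; the pipeline consumes a
user-supplied two-column tab-separated PT->SOC map following the
primary-SOC convention (exactly one SOC per PT). A toy vocabulary
covering the 25 standard system organ classes and the drug dictionary
for the anticoagulant/antiplatelet classes are bundled for testing and
demos.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .errors import DataFormatError

UNMAPPED_SOC = "unmapped"

DRUG_CLASSES = (
    "heparin_lmwh",
    "warfarin",
    "doac",
    "other_anticoagulant",
    "antiplatelet",
    "none",
)

#: Classes whose concomitant presence defines the exclusion analysis.
ANTITHROMBOTIC_CLASSES = (
    "heparin_lmwh",
    "warfarin",
    "doac",
    "other_anticoagulant",
    "antiplatelet",
)


@dataclass
class VocabularyMap:
    """PT -> single primary SOC, plus the SOC display order."""

    pt_to_soc: dict[str, str]
    soc_list: list[str]

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc.get(pt.strip().lower(), UNMAPPED_SOC)

    def coverage(self, pts: Iterable[str]) -> dict[str, bool]:
        """Which PTs resolve; unmapped ones proceed under the 'unmapped' SOC."""
        return {pt: pt.strip().lower() in self.pt_to_soc for pt in set(pts)}


def load_vocabulary(path: Path | str) -> VocabularyMap:
    """Load a two-column (PT <tab> SOC) vocabulary file.

    Duplicate PT lines are tolerated when they agree; conflicting
    duplicates raise a format error naming the offending PTs.
    """
    pt_to_soc: dict[str, str] = {}
    soc_order: list[str] = []
    conflicts: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            pt = parts[0].strip().lower()
            soc = parts[1].strip().lower()
            if pt in pt_to_soc and pt_to_soc[pt] != soc:
                conflicts.append(pt)
                continue
            pt_to_soc[pt] = soc
            if soc not in soc_order:
                soc_order.append(soc)
    if conflicts:
        raise DataFormatError(
            "PT(s) mapped to more than one SOC: " + ", ".join(sorted(set(conflicts)))
        )
    if not pt_to_soc:
        raise DataFormatError(f"empty vocabulary file: {path}")
    return VocabularyMap(pt_to_soc=pt_to_soc, soc_list=soc_order)


@dataclass
class DrugDictionary:
    """Alias -> standardized name, and standardized name -> drug class."""

    alias_to_standard: dict[str, str] = field(default_factory=dict)
    class_of: dict[str, str] = field(default_factory=dict)

    def classify(self, name_raw: str) -> tuple[str, str]:
        """(standardized name, class); unknown names pass through lowercased."""
        key = name_raw.strip().lower()
        standard = self.alias_to_standard.get(key, key)
        return standard, self.class_of.get(standard, "none")

    def drugs_in_class(self, cls: str) -> frozenset[str]:
        return frozenset(d for d, c in self.class_of.items() if c == cls)


# spec-level alias kept for the operation name used elsewhere
def classify_drug(dictionary: DrugDictionary, name_raw: str) -> tuple[str, str]:
    return dictionary.classify(name_raw)


def load_drug_dictionary(path: Path | str) -> DrugDictionary:
    """Load a three-column (alias <tab> standard <tab> class) dictionary."""
    d = DrugDictionary()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            alias, standard, cls = (p.strip().lower() for p in parts)
            if cls not in DRUG_CLASSES:
                raise DataFormatError(f"{path}:{lineno}: unknown drug class {cls!r}")
            d.alias_to_standard[alias] = standard
            d.alias_to_standard.setdefault(standard, standard)
            existing = d.class_of.get(standard)
            if existing is not None and existing != cls:
                raise DataFormatError(
                    f"{path}:{lineno}: {standard!r} assigned conflicting classes"
                )
            d.class_of[standard] = cls
    return d


def _bundled(name: str) -> Path:
    return Path(str(resources.files("faersig").joinpath("data", name)))


def load_toy_vocabulary() -> VocabularyMap:
    """The bundled toy PT->SOC map (25 SOCs, ~50 PTs)."""
    return load_vocabulary(_bundled("toy_meddra.tsv"))


def load_default_drug_dictionary() -> DrugDictionary:
    """The bundled anticoagulant/antiplatelet drug dictionary."""
    return load_drug_dictionary(_bundled("drug_dictionary.tsv"))


def load_pt_groups(path: Optional[Path | str]) -> dict[str, list[str]]:
    """Optional user-supplied grouping of clinically overlapping PTs.

    Two-column file: group label <tab> PT. Returns {label: [PTs]}.
    """
    if path is None:
        return {}
    groups: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            label, pt = (p.strip().lower() for p in line.split("\t", 1))
            groups.setdefault(label, []).append(pt)
    return groups
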