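"""Assignment of candidate chemical identities to called sites.

Reverse-transcriptase signatures only narrow the identity of a modification:
m1A reads out as A-to-T/A-to-G mismatches with strong arrest, inosine as a
clean A-to-G mismatch without arrest, the G9/G26-type methylations as G
mismatches with arrest, and so on.  Because several chemistries share a
signature, each call receives a *ranked list* of candidates: modifications
known at the same standard (Sprinzl) position in other species rank above
purely signature-compatible ones, and ambiguous sets are preserved verbatim
(a G26 call stays "m2G|m22G").  Classification is total — a call matching no
rule is labelled "unknown" with its observed signature attached — and never
drops a call.

The packaged signature table and known-position catalogue are curated
reconstructions of the published RT-signature collections; both are
user-overridable TSVs with provenance recorded per row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional

from .calling import ModificationCall

WEAK_STRONG_BOUNDARY = 0.4  # RTa intensity splitting "weak" from "strong"


@dataclass(frozen=True)
class SignatureRule:
    ref_base: str
    requires_rta: str  # yes | no | optional
    dominant_mismatch_targets: frozenset[str]  # empty = no mismatch required
    intensity_class: str  # weak | strong | any
    modification_codes: tuple[str, ...]
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if self.requires_rta not in {"yes", "no", "optional"}:
            raise ValueError(f"bad requires_rta {self.requires_rta!r}")
        if self.intensity_class not in {"weak", "strong", "any"}:
            raise ValueError(f"bad intensity_class {self.intensity_class!r}")
        if not self.modification_codes:
            raise ValueError("modification_codes must be non-empty")

    def matches(self, call: ModificationCall,
                weak_strong: float = WEAK_STRONG_BOUNDARY) -> bool:
        if call.ref_base != self.ref_base:
            return False
        if self.requires_rta == "yes" and not call.evidence_rta:
            return False
        if self.requires_rta == "no" and call.evidence_rta:
            return False
        if self.dominant_mismatch_targets:
            if not call.evidence_mismatch:
                return False
            dom = call.dominant_mismatch
            if dom is None or dom not in self.dominant_mismatch_targets:
                return False
        if self.intensity_class != "any" and call.evidence_rta:
            intensity = call.rta_intensity or 0.0
            if self.intensity_class == "weak" and intensity >= weak_strong:
                return False
            if self.intensity_class == "strong" and intensity < weak_strong:
                return False
        return True


@dataclass(frozen=True)
class KnownPositionEntry:
    sprinzl_label: str
    ref_base: str
    known_modifications: tuple[str, ...]
    provenance: str = "catalogue"


# ---------------------------------------------------------------------------
# table I/O


def _data_path(name: str):
    return resources.files("rtamod.data").joinpath(name)


def load_signature_table(path: Optional[str | Path] = None) -> list[SignatureRule]:
    """Parse a signature TSV; ``None`` loads the packaged defaults."""
    source = Path(path) if path else _data_path("signatures.tsv")
    rules = []
    with source.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            targets = row["dominant_mismatch_targets"].strip()
            rules.append(
                SignatureRule(
                    ref_base=row["ref_base"],
                    requires_rta=row["requires_rta"],
                    dominant_mismatch_targets=frozenset(
                        t for t in targets.split(",") if t and t != "-"
                    ),
                    intensity_class=row["intensity_class"],
                    modification_codes=tuple(row["modification_codes"].split(",")),
                    provenance=row.get("provenance", "user"),
                )
            )
    return rules


def save_signature_table(rules: list[SignatureRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ref_base\trequires_rta\tdominant_mismatch_targets\t"
            "intensity_class\tmodification_codes\tprovenance\n"
        )
        for r in rules:
            targets = ",".join(sorted(r.dominant_mismatch_targets)) or "-"
            fh.write(
                f"{r.ref_base}\t{r.requires_rta}\t{targets}\t{r.intensity_class}\t"
                f"{','.join(r.modification_codes)}\t{r.provenance}\n"
            )


def load_catalogue(path: Optional[str | Path] = None) -> list[KnownPositionEntry]:
    source = Path(path) if path else _data_path("catalogue.tsv")
    entries = []
    with source.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entries.append(
                KnownPositionEntry(
                    sprinzl_label=row["sprinzl_label"],
                    ref_base=row["ref_base"],
                    known_modifications=tuple(row["known_modifications"].split(",")),
                    provenance=row.get("provenance", "user"),
                )
            )
    return entries


def save_catalogue(entries: list[KnownPositionEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sprinzl_label\tref_base\tknown_modifications\tprovenance\n")
        for e in entries:
            fh.write(
                f"{e.sprinzl_label}\t{e.ref_base}\t"
                f"{','.join(e.known_modifications)}\t{e.provenance}\n"
            )


# ---------------------------------------------------------------------------
# classification


def classify_call(
    call: ModificationCall,
    rules: list[SignatureRule],
    catalogue: list[KnownPositionEntry],
    weak_strong: float = WEAK_STRONG_BOUNDARY,
) -> ModificationCall:
    """Attach ranked candidate identities and a novelty flag to a call."""
    compatible: list[str] = []
    for rule in rules:
        if rule.matches(call, weak_strong):
            for code in rule.modification_codes:
                if code not in compatible:
                    compatible.append(code)

    known_here: list[str] = []
    if call.sprinzl_label is not None:
        for e in catalogue:
            if e.sprinzl_label == call.sprinzl_label and e.ref_base == call.ref_base:
                known_here.extend(
                    m for m in e.known_modifications if m not in known_here
                )

    # rank: signature-compatible AND catalogued at this position first,
    # then remaining signature-compatible, preserving table order
    ranked = [c for c in known_here if c in compatible]
    ranked += [c for c in compatible if c not in ranked]
    if not ranked:
        sig = "/".join(
            f"{call.ref_base}>{b}" for b in sorted(call.mismatch_spectrum)
        )
        ranked = [f"unknown({sig})" if sig else "unknown"]

    return replace(
        call,
        candidate_identities=ranked,
        novelty=novelty_flag(call, catalogue),
    )


def novelty_flag(
    call: ModificationCall, catalogue: list[KnownPositionEntry]
) -> str:
    """"known_position" when (label, ref_base) is catalogued, else "novel_position"."""
    if call.sprinzl_label is None:
        return "novel_position(unlabeled)"
    for e in catalogue:
        if e.sprinzl_label == call.sprinzl_label and e.ref_base == call.ref_base:
            return "known_position"
    return "novel_position"


def classify_calls(
    calls: list[ModificationCall],
    rules: Optional[list[SignatureRule]] = None,
    catalogue: Optional[list[KnownPositionEntry]] = None,
    weak_strong: float = WEAK_STRONG_BOUNDARY,
) -> list[ModificationCall]:
    rules = rules if rules is not None else load_signature_table()
    catalogue = catalogue if catalogue is not None else load_catalogue()
    return [classify_call(c, rules, catalogue, weak_strong) for c in calls]
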