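"""Pedigree co-segregation calls and population-control screening.

The model is a fully penetrant autosomal-dominant trait: a variant segregates
perfectly when every genotyped affected individual carries at least one
alternate allele and no genotyped unaffected individual carries any.  Missing
genotypes make the call indeterminate rather than silently dropping samples,
so the outcome is three-valued (yes / no / unknown).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .variant_io import CandidateVariant, Pedigree, VariantKey

GENOTYPES = {"ref/ref", "ref/alt", "alt/alt", "missing"}

_ALT_COUNT = {"ref/ref": 0, "ref/alt": 1, "alt/alt": 2}


class SegregationCall(enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass
class GenotypePanel:
    """Genotypes of pedigree members at candidate loci."""

    genotypes: dict[tuple[str, VariantKey], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (sample, key), gt in self.genotypes.items():
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype {gt!r} for {sample} at {key}")

    def set(self, sample: str, key: VariantKey, gt: str) -> None:
        if gt not in GENOTYPES:
            raise ValueError(f"unknown genotype {gt!r}")
        self.genotypes[(sample, key)] = gt

    def get(self, sample: str, key: VariantKey) -> Optional[str]:
        return self.genotypes.get((sample, key))

    def samples_typed_at(self, key: VariantKey) -> list[str]:
        return [s for (s, k) in self.genotypes if k == key]

    def variants(self) -> set[VariantKey]:
        return {k for (_, k) in self.genotypes}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypePanel":
        """Columns: sample, chrom, pos, ref, alt, genotype."""
        panel = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            )
            for rec in reader:
                key = (rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
                panel.set(rec["sample"], key, rec["genotype"])
        return panel

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample", "chrom", "pos", "ref", "alt", "genotype"])
            for (sample, key), gt in sorted(self.genotypes.items()):
                writer.writerow([sample, *key, gt])


@dataclass(frozen=True)
class ControlScreenResult:
    """Carrier/allele tallies of one variant in a population-control cohort."""

    key: VariantKey
    n_controls: int
    het_carriers: int
    hom_carriers: int

    def __post_init__(self) -> None:
        if self.carrier_count > self.n_controls:
            raise ValueError("carrier count exceeds number of controls")

    @property
    def carrier_count(self) -> int:
        return self.het_carriers + self.hom_carriers

    @property
    def carrier_frequency(self) -> float:
        return self.carrier_count / self.n_controls if self.n_controls else 0.0

    @property
    def allele_frequency(self) -> float:
        """(het + 2 x hom alleles) / (2 x n_controls)."""
        if self.n_controls == 0:
            return 0.0
        return (self.het_carriers + 2 * self.hom_carriers) / (2 * self.n_controls)


def segregates(
    key: VariantKey, panel: GenotypePanel, pedigree: Pedigree
) -> SegregationCall:
    """Perfect-segregation test under a fully penetrant dominant model.

    YES iff every genotyped affected carries >= 1 alternate allele and every
    genotyped unaffected carries none.  A single contradicting genotype gives
    NO regardless of missingness; otherwise any missing genotype among the
    typed samples gives UNKNOWN.
    """
    typed = panel.samples_typed_at(key)
    if not typed:
        raise KeyError(f"variant {key} absent from genotype panel")
    any_missing = False
    for sample in typed:
        status = pedigree[sample].status
        if status == "unknown":
            raise ValueError(f"sample {sample} has no affection status")
        gt = panel.get(sample, key)
        if gt == "missing":
            any_missing = True
            continue
        alt = _ALT_COUNT[gt]
        if status == "affected" and alt == 0:
            return SegregationCall.NO
        if status == "unaffected" and alt > 0:
            return SegregationCall.NO
    return SegregationCall.UNKNOWN if any_missing else SegregationCall.YES


def control_screen(
    key: VariantKey,
    cohort_genotypes: Iterable[str],
    n_controls: Optional[int] = None,
) -> ControlScreenResult:
    """Tally carriers of ``key`` in a control cohort.

    ``cohort_genotypes`` is the genotype vector of the screened controls
    (``ref/ref`` / ``ref/alt`` / ``alt/alt``; ``missing`` entries reduce the
    effective denominator unless ``n_controls`` is given explicitly).
    """
    het = hom = typed = 0
    for gt in cohort_genotypes:
        if gt == "missing":
            continue
        typed += 1
        alt = _ALT_COUNT[gt]
        if alt == 1:
            het += 1
        elif alt == 2:
            hom += 1
    return ControlScreenResult(
        key=key,
        n_controls=n_controls if n_controls is not None else typed,
        het_carriers=het,
        hom_carriers=hom,
    )


_PREDICTION_RANK = {
    "probably_damaging": 3,
    "possibly_damaging": 2,
    "unknown": 1,
    None: 1,
    "benign": 0,
}

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(chrom.removeprefix("chr"), 99), chrom)


def shortlist(
    candidates: Sequence[CandidateVariant],
    screen_results: Mapping[VariantKey, ControlScreenResult],
) -> list[CandidateVariant]:
    """Rank perfectly segregating candidates.

    Keeps candidates whose ``segregation_flag`` is True and sorts by
    (absent from controls, damaging prediction, GERP descending), breaking
    ties deterministically by (chrom, pos).  A candidate with no screen
    result is treated as unscreened (carrier count unknown -> ranked after
    zero-carrier candidates with equal annotation).
    """
    kept = [c for c in candidates if c.segregation_flag]

    def sort_key(c: CandidateVariant):
        res = screen_results.get(c.key)
        absent = res is not None and res.carrier_count == 0
        pred = _PREDICTION_RANK.get(c.call.prediction, 1)
        gerp = c.gerp if c.gerp is not None else float("-inf")
        return (
            0 if absent else 1,
            -pred,
            -gerp,
            _chrom_sort_key(c.call.chrom),
            c.call.pos,
        )

    return sorted(kept, key=sort_key)
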