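"""Variant, sample and pedigree data model with TSV / minimal-VCF / PED readers.

Coordinates are 1-based inclusive throughout; the genome build is carried as an
opaque metadata label (no liftover is attempted).  Indels are represented with
explicit payloads the way the candidate table prints them (``-AA``, ``+CTC``,
``-TTTTA``) with ``*`` as the reference placeholder.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

VAR_CLASSES = {
    "missense",
    "nonsense",
    "splice",
    "synonymous",
    "intronic",
    "intergenic",
    "frameshift",
    "coding-indel",
}

PREDICTIONS = {"benign", "possibly_damaging", "probably_damaging", "unknown"}

VariantKey = tuple[str, int, str, str]


class FormatError(ValueError):
    """A file violated the declared dialect (bad header, bad column, bad row)."""


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unresolved parent, cyclic parentage)."""


@dataclass
class VariantCall:
    """One observed variant in one sample.

    ``db_flags`` maps database labels (``dbSNP``, ``HapMap``, ``KG``) to the
    observed population frequency of the variant in that database.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Literal["het", "hom"] = "het"
    depth: Optional[int] = None
    qual: Optional[float] = None
    var_class: Optional[str] = None
    db_flags: dict[str, float] = field(default_factory=dict)
    prediction: Optional[str] = None
    gene: Optional[str] = None
    build: str = "hg19"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.var_class is not None and self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if self.prediction is not None and self.prediction not in PREDICTIONS:
            raise ValueError(f"unknown prediction {self.prediction!r}")
        for db, freq in self.db_flags.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"{db} frequency {freq} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.alt.startswith(("+", "-")) or self.ref == "*"

    def max_db_freq(self) -> Optional[float]:
        """Highest frequency across databases, or None if absent everywhere."""
        return max(self.db_flags.values()) if self.db_flags else None


@dataclass
class SampleExome:
    """Per-individual variant set with the sample's disease status."""

    sample_id: str
    status: Literal["affected", "unaffected"]
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[VariantKey] = set()
        for call in self.calls:
            if call.key in seen:
                raise ValueError(
                    f"duplicate variant {call.key} in sample {self.sample_id}"
                )
            seen.add(call.key)

    def __len__(self) -> int:
        return len(self.calls)

    def key_set(self) -> set[VariantKey]:
        return {c.key for c in self.calls}

    def by_key(self) -> dict[VariantKey, VariantCall]:
        return {c.key: c for c in self.calls}

    def replaced(self, calls: list[VariantCall]) -> "SampleExome":
        return SampleExome(self.sample_id, self.status, calls)


@dataclass
class CandidateVariant:
    """A cascade survivor annotated for the segregation stage."""

    call: VariantCall
    segregation_flag: Optional[bool] = None
    gerp: Optional[float] = None
    aa_subst: Optional[str] = None

    @property
    def key(self) -> VariantKey:
        return self.call.key


@dataclass
class Individual:
    iid: str
    sex: Literal["male", "female", "unknown"] = "unknown"
    father: Optional[str] = None
    mother: Optional[str] = None
    status: Literal["affected", "unaffected", "unknown"] = "unknown"
    age_class: Optional[str] = None


class Pedigree:
    """A pedigree with relationship queries and kinship coefficients.

    The kinship coefficient ``phi(a, b)`` is the probability that a random
    allele sampled from ``a`` is identical by descent with a random allele
    sampled from ``b``; it is computed by the classical recursion on parents.
    """

    def __init__(self, members: Iterable[Individual]):
        self.members: dict[str, Individual] = {}
        for m in members:
            if m.iid in self.members:
                raise PedigreeError(f"duplicate individual {m.iid}")
            self.members[m.iid] = m
        for m in self.members.values():
            for parent in (m.father, m.mother):
                if parent is not None and parent not in self.members:
                    raise PedigreeError(
                        f"{m.iid}: parent {parent} not in pedigree"
                    )
        self._check_acyclic()
        self._depth_cache: dict[str, int] = {}
        self._kinship_cache: dict[tuple[str, str], float] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: set[str]) -> None:
            if iid in stack:
                raise PedigreeError(f"cyclic parentage involving {iid}")
            if state.get(iid) == 1:
                return
            stack.add(iid)
            m = self.members[iid]
            for parent in (m.father, m.mother):
                if parent is not None:
                    visit(parent, stack)
            stack.discard(iid)
            state[iid] = 1

        for iid in self.members:
            visit(iid, set())

    # -- structure ---------------------------------------------------------
    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __getitem__(self, iid: str) -> Individual:
        return self.members[iid]

    def founders(self) -> list[str]:
        return [
            iid
            for iid, m in self.members.items()
            if m.father is None and m.mother is None
        ]

    def affected(self) -> list[str]:
        return [i for i, m in self.members.items() if m.status == "affected"]

    def unaffected(self) -> list[str]:
        return [i for i, m in self.members.items() if m.status == "unaffected"]

    def depth(self, iid: str) -> int:
        if iid not in self._depth_cache:
            m = self.members[iid]
            parents = [p for p in (m.father, m.mother) if p is not None]
            self._depth_cache[iid] = (
                0 if not parents else 1 + max(self.depth(p) for p in parents)
            )
        return self._depth_cache[iid]

    def topological_order(self) -> list[str]:
        return sorted(self.members, key=self.depth)

    # -- relationships -----------------------------------------------------
    def are_siblings(self, a: str, b: str) -> bool:
        ma, mb = self.members[a], self.members[b]
        return (
            a != b
            and ma.father is not None
            and ma.mother is not None
            and ma.father == mb.father
            and ma.mother == mb.mother
        )

    def are_first_cousins(self, a: str, b: str) -> bool:
        ma, mb = self.members[a], self.members[b]
        pa = [p for p in (ma.father, ma.mother) if p is not None]
        pb = [p for p in (mb.father, mb.mother) if p is not None]
        if set(pa) & set(pb):  # siblings or half-siblings, not cousins
            return False
        return any(self.are_siblings(x, y) for x in pa for y in pb)

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient by the recursive path-counting algorithm."""
        key = (a, b) if a <= b else (b, a)
        if key in self._kinship_cache:
            return self._kinship_cache[key]
        if a == b:
            m = self.members[a]
            inbreeding = (
                self.kinship(m.father, m.mother)
                if m.father is not None and m.mother is not None
                else 0.0
            )
            phi = 0.5 * (1.0 + inbreeding)
        else:
            # recurse on the individual further from the founders
            if self.depth(a) < self.depth(b):
                a, b = b, a
            m = self.members[a]
            if m.father is None and m.mother is None:
                phi = 0.0
            else:
                phi = 0.0
                for parent in (m.father, m.mother):
                    phi += 0.5 * (self.kinship(parent, b) if parent else 0.0)
        self._kinship_cache[key] = phi
        return phi


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "zygosity", "depth", "qual",
                "var_class", "gene", "prediction", "db_flags"]
_MANDATORY = ["chrom", "pos", "ref", "alt"]


def _parse_db_flags(text: str) -> dict[str, float]:
    flags: dict[str, float] = {}
    if text and text != ".":
        for item in text.split(";"):
            db, _, freq = item.partition(":")
            flags[db] = float(freq) if freq else 0.0
    return flags


def _format_db_flags(flags: dict[str, float]) -> str:
    if not flags:
        return "."
    return ";".join(f"{db}:{freq!r}" for db, freq in sorted(flags.items()))


def read_variant_table(
    path: str | Path,
    dialect: Literal["tsv", "vcf_subset"] = "tsv",
    sample_id: Optional[str] = None,
    status: Optional[str] = None,
) -> SampleExome:
    """Read one sample's variant calls from a TSV table or a minimal VCF.

    Malformed rows raise :class:`FormatError` naming the offending line.
    ``sample_id``/``status`` override any ``#sample_id=``/``#status=``
    header comments (TSV dialect) or the VCF sample name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path, sample_id, status)
    if dialect == "vcf_subset":
        return _read_vcf_subset(path, sample_id, status)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path, sample_id: Optional[str], status: Optional[str]) -> SampleExome:
    meta: dict[str, str] = {}
    rows: list[tuple[int, dict[str, str]]] = []
    with open(path, newline="") as fh:
        header: Optional[list[str]] = None
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#") and header is None):
                if row and "=" in row[0]:
                    k, _, v = row[0].lstrip("#").partition("=")
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = row
                missing = [c for c in _MANDATORY if c not in header]
                if missing:
                    raise FormatError(
                        f"{path}: missing mandatory column(s) {', '.join(missing)}"
                    )
                continue
            rows.append((lineno, dict(zip(header, row))))
    if header is None:
        raise FormatError(f"{path}: no header line found")

    calls: list[VariantCall] = []
    for lineno, rec in rows:
        try:
            zyg = rec.get("zygosity", "het") or "het"
            if zyg not in ("het", "hom"):
                raise ValueError(f"unknown zygosity code {zyg!r}")
            calls.append(
                VariantCall(
                    chrom=rec["chrom"],
                    pos=int(rec["pos"].replace(",", "")),
                    ref=rec["ref"],
                    alt=rec["alt"],
                    zygosity=zyg,
                    depth=int(rec["depth"]) if rec.get("depth") not in (None, "", ".") else None,
                    qual=float(rec["qual"]) if rec.get("qual") not in (None, "", ".") else None,
                    var_class=rec.get("var_class") or None,
                    gene=rec.get("gene") or None,
                    prediction=(rec.get("prediction") or None) if rec.get("prediction") != "." else None,
                    db_flags=_parse_db_flags(rec.get("db_flags", "")),
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed record: {exc}") from exc
    return SampleExome(
        sample_id=sample_id or meta.get("sample_id", path.stem),
        status=status or meta.get("status", "unaffected"),  # type: ignore[arg-type]
        calls=calls,
    )


def _read_vcf_subset(path: Path, sample_id: Optional[str], status: Optional[str]) -> SampleExome:
    """Minimal VCF: CHROM/POS/REF/ALT/QUAL plus FORMAT GT and DP of one sample.

    Optional INFO keys CLASS, GENE and PRED populate the annotation fields;
    everything else passes through untouched.
    """
    import pysam

    def info_field(rec, key):
        try:
            return rec.info.get(key)
        except (KeyError, ValueError):  # key not declared in the header
            return None

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample column")
        name = sample_id if sample_id in samples else samples[0]
        for rec in vcf:
            gt = rec.samples[name].get("GT", (None, None))
            alleles = [a for a in gt if a is not None]
            if not alleles or not any(alleles):
                continue
            zyg = "hom" if alleles.count(alleles[0]) == len(alleles) and alleles[0] != 0 and len(alleles) > 1 else "het"
            alt = rec.alts[0] if rec.alts else "."
            calls.append(
                VariantCall(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(alt),
                    zygosity=zyg,
                    depth=rec.samples[name].get("DP"),
                    qual=float(rec.qual) if rec.qual is not None else None,
                    var_class=info_field(rec, "CLASS"),
                    gene=info_field(rec, "GENE"),
                    prediction=info_field(rec, "PRED"),
                )
            )
    return SampleExome(
        sample_id=sample_id or name,
        status=status or "unaffected",  # type: ignore[arg-type]
        calls=calls,
    )


def write_variant_table(exome: SampleExome, path: str | Path) -> None:
    """Write a TSV the :func:`read_variant_table` reader round-trips exactly."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"#sample_id={exome.sample_id}\n")
        fh.write(f"#status={exome.status}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for c in exome.calls:
            writer.writerow(
                [
                    c.chrom,
                    c.pos,
                    c.ref,
                    c.alt,
                    c.zygosity,
                    c.depth if c.depth is not None else ".",
                    repr(c.qual) if c.qual is not None else ".",
                    c.var_class or "",
                    c.gene or "",
                    c.prediction or ".",
                    _format_db_flags(c.db_flags),
                ]
            )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (fam, iid, father, mother, sex, phenotype)."""
    members: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 PED columns")
            _, iid, father, mother, sex, pheno = parts[:6]
            members.append(
                Individual(
                    iid=iid,
                    sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                    father=None if father in ("0", ".") else father,
                    mother=None if mother in ("0", ".") else mother,
                    status={"1": "unaffected", "2": "affected"}.get(pheno, "unknown"),
                )
            )
    return Pedigree(members)


def write_pedigree(ped: Pedigree, path: str | Path, fam: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for iid in ped.topological_order():
            m = ped[iid]
            sex = {"male": "1", "female": "2"}.get(m.sex, "0")
            pheno = {"unaffected": "1", "affected": "2"}.get(m.status, "0")
            fh.write(
                f"{fam}\t{iid}\t{m.father or '0'}\t{m.mother or '0'}\t{sex}\t{pheno}\n"
            )


# ---------------------------------------------------------------------------
# transcribed study fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("ancl_exome.data").joinpath(name)


def load_attrition_counts():
    """The published per-sample filtering counts, as a pandas DataFrame.

    These counts are *inputs* transcribed from the study report: the family's
    raw exomes are private, so the counts cannot be recomputed here.  They
    feed the attrition arithmetic only.
    """
    import pandas as pd

    with resources.as_file(_data_path("attrition_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_candidate_table() -> list[CandidateVariant]:
    """The 22 validated candidate variants (19 SNSs + 3 indels), transcribed.

    Positions follow human genome build 37 as printed; the ``segregates``
    column is the published extended-segregation call.
    """
    candidates: list[CandidateVariant] = []
    with resources.as_file(_data_path("candidate_variants.tsv")) as p:
        with open(p, newline="") as fh:
            reader = csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            )
            for rec in reader:
                call = VariantCall(
                    chrom=rec["chrom"],
                    pos=int(rec["pos"]),
                    ref=rec["ref"],
                    alt=rec["alt"],
                    var_class=rec["var_class"],
                    prediction=rec["prediction"] if rec["prediction"] != "." else None,
                    gene=rec["gene"],
                    build="hg19",
                )
                candidates.append(
                    CandidateVariant(
                        call=call,
                        segregation_flag=rec["segregates"] == "yes",
                        gerp=float(rec["gerp"]) if rec["gerp"] != "." else None,
                        aa_subst=rec["aa_subst"] if rec["aa_subst"] != "." else None,
                    )
                )
    return candidates
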