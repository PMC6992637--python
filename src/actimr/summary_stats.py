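"""GWAS summary-statistic data model, file I/O, and allele harmonisation.

The unit of data is a :class:`SnpAssociation` — one SNP's association with
one trait.  An :class:`Instrument` bundles the associations used as genetic
proxies for an exposure, and :func:`harmonise` aligns exposure and outcome
records to a common effect allele, which is the prerequisite for every
two-sample estimator in :mod:`actimr.mr_estimators`.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .errors import (
    ConfigurationError,
    EmptyInputError,
    HarmonisationError,
    UnknownInstrumentError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window inside which a palindromic SNP cannot be oriented by frequency
PALINDROME_AMBIGUITY_WINDOW = (0.42, 0.58)

#: canonical field -> default column header
DEFAULT_DIALECT = {
    "rsid": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "chromosome": "chr",
    "position": "position",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "n": "n",
    "pvalue": "pvalue",
}

_MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "n")
_OPTIONAL_FIELDS = ("chromosome", "position", "pvalue")


@dataclass
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is per copy of ``effect_allele``: for a continuous exposure it is
    on the measurement (or SD) scale, for a binary outcome it is a log odds
    ratio.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n: int
    chromosome: str | None = None
    position: int | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.se <= 0.0:
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.n < 2:
            raise ValueError(f"{self.rsid}: n must be >= 2, got {self.n}")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "SnpAssociation":
        """Return the same association expressed per copy of the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class Instrument:
    """A named set of exposure-associated variants with strength metadata.

    ``r2_formula`` selects how per-variant variance explained is computed:
    ``"simple"`` = 2·EAF·(1−EAF)·beta² (valid when beta is in SD units),
    ``"from_se"`` = beta²-vs-sampling-variance form that is scale invariant.
    """

    name: str
    variants: list[SnpAssociation]
    exposure_unit: str = "sd"  # "sd" | "milligravity"
    r2_formula: str = "from_se"
    variance_explained: float = field(init=False)

    def __post_init__(self) -> None:
        if self.r2_formula not in ("simple", "from_se"):
            raise ConfigurationError(f"unknown r2 formula {self.r2_formula!r}")
        if self.exposure_unit not in ("sd", "milligravity"):
            raise ConfigurationError(f"unknown exposure unit {self.exposure_unit!r}")
        seen: set[str] = set()
        for v in self.variants:
            if v.rsid in seen:
                raise ValueError(f"duplicate rsid {v.rsid} in instrument {self.name}")
            seen.add(v.rsid)
        self.variance_explained = float(sum(self.per_variant_r2()))

    def per_variant_r2(self) -> list[float]:
        from .instrument_strength import r2_from_se, r2_simple

        if self.r2_formula == "simple":
            return [r2_simple(v.eaf, v.beta) for v in self.variants]
        return [r2_from_se(v.eaf, v.beta, v.se, v.n) for v in self.variants]

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class TraitBlock:
    """Per-trait beta/se/eaf/n aligned to a harmonised effect allele."""

    beta: float
    se: float
    eaf: float
    n: int


@dataclass
class HarmonisedVariant:
    """An exposure/outcome(s) SNP pair expressed per a common effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    exposure: TraitBlock
    outcomes: dict[str, TraitBlock]
    flipped: dict[str, bool]
    palindromic: bool = False


@dataclass
class HarmonisationResult:
    """Harmonised variants plus an audit trail of dropped SNPs."""

    variants: list[HarmonisedVariant]
    dropped: list[tuple[str, str]]  # (rsid, reason)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# File I/O


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_summary_stats(
    path, dialect: Mapping[str, str] | None = None
) -> list[SnpAssociation]:
    """Read a delimited summary-statistics file into SnpAssociation records.

    ``dialect`` maps canonical field names (rsid, effect_allele, ...) to the
    file's column headers; unmapped optional fields are taken from the default
    header names when present.  Rows whose numeric fields fail to parse are
    rejected with a logged, row-indexed warning rather than aborting the read.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise EmptyInputError(f"{path}: empty file")
        sep = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=sep)
        header = reader.fieldnames or []
        for key in _MANDATORY_FIELDS:
            if dialect[key] not in header:
                raise ConfigurationError(
                    f"{path}: mandatory column {dialect[key]!r} (field {key}) missing"
                )
        records: list[SnpAssociation] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):  # 1-based, header is line 1
            try:
                rec = _parse_row(row, dialect, header)
            except (ValueError, TypeError) as exc:
                logger.warning("%s: row %d rejected: %s", path, i, exc)
                warnings.warn(f"{path}: row {i} rejected: {exc}", stacklevel=2)
                continue
            if rec.rsid in seen:
                warnings.warn(
                    f"{path}: duplicate rsid {rec.rsid} at row {i}; keeping first",
                    stacklevel=2,
                )
                continue
            seen.add(rec.rsid)
            records.append(rec)
    if not records:
        raise EmptyInputError(f"{path}: no parseable data rows")
    return records


def _parse_row(row, dialect, header) -> SnpAssociation:
    def get(fieldname):
        col = dialect[fieldname]
        return row.get(col) if col in header else None

    kwargs = {
        "rsid": str(get("rsid")).strip(),
        "effect_allele": str(get("effect_allele")).strip(),
        "other_allele": str(get("other_allele")).strip(),
        "eaf": float(get("eaf")),
        "beta": float(get("beta")),
        "se": float(get("se")),
        "n": int(float(get("n"))),
    }
    chrom = get("chromosome")
    if chrom not in (None, ""):
        kwargs["chromosome"] = str(chrom).strip()
    pos = get("position")
    if pos not in (None, ""):
        kwargs["position"] = int(float(pos))
    pv = get("pvalue")
    if pv not in (None, ""):
        kwargs["pvalue"] = float(pv)
    return SnpAssociation(**kwargs)


def write_summary_stats(
    records: Iterable[SnpAssociation], path, sep: str = "\t"
) -> None:
    """Write records as delimited text, floats at 12 significant digits."""
    records = list(records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(
            ["SNP", "effect_allele", "other_allele", "chr", "position",
             "eaf", "beta", "se", "n", "pvalue"]
        )
        for r in records:
            writer.writerow(
                [
                    r.rsid,
                    r.effect_allele,
                    r.other_allele,
                    r.chromosome if r.chromosome is not None else "",
                    r.position if r.position is not None else "",
                    format(r.eaf, ".12g"),
                    format(r.beta, ".12g"),
                    format(r.se, ".12g"),
                    r.n,
                    format(r.pvalue, ".12g") if r.pvalue is not None else "",
                ]
            )


# ---------------------------------------------------------------------------
# Built-in instruments

_BUILTIN_FILES = {
    # 5-SNP instrument: betas are ~8x smaller than the 10-SNP instrument's and
    # behave as SD units; the variance-explained formula matching the reported
    # per-variant R2 is the simple 2pq*beta^2 form.
    "doherty5": ("doherty5.tsv", "sd", "simple"),
    "klimentidis10": ("klimentidis10.tsv", "milligravity", "from_se"),
}


def builtin_instrument(name: str) -> Instrument:
    """Return one of the packaged physical-activity instruments.

    Known names: ``doherty5`` (5 genome-wide-significant SNPs, N = 91,105)
    and ``klimentidis10`` (10-SNP extended instrument, N = 91,084).
    """
    try:
        fname, unit, formula = _BUILTIN_FILES[name]
    except KeyError:
        raise UnknownInstrumentError(
            f"unknown instrument {name!r}; known: {sorted(_BUILTIN_FILES)}"
        ) from None
    ref = resources.files("actimr").joinpath("data", fname)
    with resources.as_file(ref) as p:
        variants = read_summary_stats(
            p, dialect={"chromosome": "chr"}
        )
    return Instrument(name=name, variants=variants, exposure_unit=unit, r2_formula=formula)


# ---------------------------------------------------------------------------
# Harmonisation


def _alleles_match(ea1, oa1, ea2, oa2) -> str | None:
    """Classify how (ea2, oa2) relates to (ea1, oa1).

    Returns 'same', 'swapped', 'comp_same', 'comp_swapped' or None.
    Complement matching is attempted only after direct matching fails.
    """
    if (ea2, oa2) == (ea1, oa1):
        return "same"
    if (ea2, oa2) == (oa1, ea1):
        return "swapped"
    cea2, coa2 = _COMPLEMENT[ea2], _COMPLEMENT[oa2]
    if (cea2, coa2) == (ea1, oa1):
        return "comp_same"
    if (cea2, coa2) == (oa1, ea1):
        return "comp_swapped"
    return None


def harmonise(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindrome_policy: str = "infer_by_eaf",
    outcome_name: str = "outcome",
) -> HarmonisationResult:
    """Align outcome records to the exposure effect allele per shared rsid.

    For each rsid present in both inputs the outcome beta is re-expressed per
    copy of the exposure effect allele (sign flip + eaf complement when the
    outcome was recorded on the opposite allele).  Palindromic (A/T, C/G)
    variants are handled per ``palindrome_policy``:

    - ``drop_ambiguous``: always dropped;
    - ``infer_by_eaf``: dropped only when either eaf falls inside the
      ambiguity window; otherwise oriented by matching the minor allele;
    - ``keep``: harmonised by nominal allele labels (strand assumed shared).
    """
    if palindrome_policy not in ("drop_ambiguous", "infer_by_eaf", "keep"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    out_by_rsid = {}
    for rec in outcome:
        out_by_rsid.setdefault(rec.rsid, rec)
    if not any(v.rsid in out_by_rsid for v in exposure):
        raise EmptyInputError("no overlapping rsids between exposure and outcome")

    variants: list[HarmonisedVariant] = []
    dropped: list[tuple[str, str]] = []
    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            dropped.append((exp.rsid, "absent_from_outcome"))
            continue
        palindromic = exp.is_palindromic
        if palindromic and palindrome_policy == "drop_ambiguous":
            dropped.append((exp.rsid, "palindromic"))
            continue
        kind = _alleles_match(
            exp.effect_allele, exp.other_allele, out.effect_allele, out.other_allele
        )
        if kind is None:
            raise HarmonisationError(
                f"{exp.rsid}: outcome alleles {out.effect_allele}/{out.other_allele} "
                f"incompatible with exposure {exp.effect_allele}/{exp.other_allele}"
            )
        if palindromic:
            # same and comp_swapped are indistinguishable by labels; resolve
            # by eaf under infer_by_eaf, by labels under keep
            if palindrome_policy == "infer_by_eaf":
                lo, hi = PALINDROME_AMBIGUITY_WINDOW
                if lo < exp.eaf < hi or lo < out.eaf < hi:
                    dropped.append((exp.rsid, "palindromic_ambiguous_eaf"))
                    continue
                flip = (exp.eaf < 0.5) != (out.eaf < 0.5)
            else:  # keep
                flip = kind in ("swapped", "comp_swapped")
        else:
            flip = kind in ("swapped", "comp_swapped")
        out_block = TraitBlock(
            beta=-out.beta if flip else out.beta,
            se=out.se,
            eaf=1.0 - out.eaf if flip else out.eaf,
            n=out.n,
        )
        variants.append(
            HarmonisedVariant(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                exposure=TraitBlock(beta=exp.beta, se=exp.se, eaf=exp.eaf, n=exp.n),
                outcomes={outcome_name: out_block},
                flipped={outcome_name: flip},
                palindromic=palindromic,
            )
        )
    return HarmonisationResult(variants=variants, dropped=dropped)


def write_harmonised(result: HarmonisationResult, path, sep: str = "\t") -> None:
    """Write a harmonised dataset (one row per variant/outcome) as text."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(
            ["SNP", "effect_allele", "other_allele", "beta_exp", "se_exp",
             "eaf_exp", "n_exp", "outcome", "beta_out", "se_out", "eaf_out",
             "n_out", "flipped", "palindromic"]
        )
        for v in result.variants:
            for name, blk in v.outcomes.items():
                writer.writerow(
                    [v.rsid, v.effect_allele, v.other_allele,
                     format(v.exposure.beta, ".12g"), format(v.exposure.se, ".12g"),
                     format(v.exposure.eaf, ".12g"), v.exposure.n,
                     name, format(blk.beta, ".12g"), format(blk.se, ".12g"),
                     format(blk.eaf, ".12g"), blk.n,
                     int(v.flipped[name]), int(v.palindromic)]
                )
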