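"""SNP genotype matrices, allele-call encoding, and SNP panel construction.

Dosages follow the 0 / 0.5 / 1 convention for AA / Aa / aa. Panels come in
three kinds:

* ``targeted`` — exactly a user-supplied list of trait-associated SNPs,
* ``random``  — a fresh uniform draw without replacement,
* ``augmented`` — the full targeted core plus random non-targeted fill,
  used to probe how dilution with uninformative markers degrades the
  embedding predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SNPPanel",
    "encode_alleles",
    "decode_alleles",
    "load_genotypes",
    "select_panel",
]

_CALL_TO_DOSAGE = {"AA": 0.0, "Aa": 0.5, "aA": 0.5, "aa": 1.0}
_DOSAGE_TO_CALL = {0.0: "AA", 0.5: "Aa", 1.0: "aa"}
_VALID_DOSAGES = np.array([0.0, 0.5, 1.0])


@dataclass
class GenotypeMatrix:
    """A samples x SNPs dosage matrix with identifiers.

    Values must lie in {0, 0.5, 1}; identifiers must be unique. Missing
    data never enters silently — see :func:`encode_alleles`.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP identifiers")
        if not np.isin(self.values, _VALID_DOSAGES).all():
            bad = self.values[~np.isin(self.values, _VALID_DOSAGES)]
            raise ValueError(f"dosages outside {{0, 0.5, 1}}: e.g. {bad.flat[0]!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = self._snp_indices(snp_ids)
        return GenotypeMatrix(list(self.sample_ids), list(snp_ids), self.values[:, idx])

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.snp_ids), self.values[idx])

    def _snp_indices(self, snp_ids: list[str]) -> list[int]:
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in pos]
        if missing:
            raise KeyError(f"SNPs not in matrix: {missing[:5]}")
        return [pos[s] for s in snp_ids]

    def row(self, sample_id: str) -> pd.Series:
        if sample_id not in self.sample_ids:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        return pd.Series(
            self.values[self.sample_ids.index(sample_id)], index=self.snp_ids
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.snp_ids)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "genotype_id"
        df.to_csv(path)


def encode_alleles(
    calls,
    missing_token: str | None = None,
    impute: str | None = None,
) -> GenotypeMatrix:
    """Encode string allele calls (AA / Aa / aA / aa) to dosages.

    ``calls`` is a DataFrame (index = sample ids, columns = SNP ids) or a
    2-D array of strings. Unknown tokens fail with the offending cell named.
    A ``missing_token`` is only tolerated when ``impute='mean'`` is enabled,
    in which case missing cells get the per-SNP mean dosage rounded to the
    nearest valid level (so the {0, 0.5, 1} invariant still holds).
    """
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        arr = np.asarray(calls, dtype=object)
        df = pd.DataFrame(
            arr,
            index=[f"S{i + 1}" for i in range(arr.shape[0])],
            columns=[f"snp{j + 1}" for j in range(arr.shape[1])],
        )
    values = np.empty(df.shape, dtype=float)
    missing_mask = np.zeros(df.shape, dtype=bool)
    raw = df.to_numpy(dtype=object)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = str(raw[i, j])
            if missing_token is not None and tok == missing_token:
                if impute != "mean":
                    raise ValueError(
                        f"missing call at sample {df.index[i]!r}, SNP "
                        f"{df.columns[j]!r}; enable impute='mean' to fill it"
                    )
                missing_mask[i, j] = True
                values[i, j] = np.nan
            elif tok in _CALL_TO_DOSAGE:
                values[i, j] = _CALL_TO_DOSAGE[tok]
            else:
                raise ValueError(
                    f"unknown allele call {tok!r} at sample {df.index[i]!r}, "
                    f"SNP {df.columns[j]!r}"
                )
    if missing_mask.any():
        for j in range(values.shape[1]):
            col = values[:, j]
            if np.isnan(col).all():
                raise ValueError(f"SNP {df.columns[j]!r} has no observed calls")
            mean = np.nanmean(col)
            col[np.isnan(col)] = _VALID_DOSAGES[np.argmin(np.abs(_VALID_DOSAGES - mean))]
    return GenotypeMatrix(list(df.index), list(df.columns), values)


def decode_alleles(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Inverse of :func:`encode_alleles` on dosages (heterozygotes -> 'Aa')."""
    decoded = np.vectorize(_DOSAGE_TO_CALL.get)(matrix.values)
    return pd.DataFrame(decoded, index=matrix.sample_ids, columns=matrix.snp_ids)


def _load_csv(path: Path) -> GenotypeMatrix:
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header or len(header) < 2:
        raise ValueError(f"{path}: no SNP columns found (malformed header?)")
    snp_header = header[1:]
    dups = sorted({s for s in snp_header if snp_header.count(s) > 1})
    if dups:
        raise ValueError(f"{path}: duplicated SNP columns {dups[:5]}")
    df = pd.read_csv(path, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric genotype values ({exc})") from exc
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns), values)


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic site {variant.CHROM}:{variant.POS} "
                f"(ALT={variant.ALT}); only biallelic SNPs are supported"
            )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types)
        if (gt == 2).any():
            raise ValueError(
                f"missing genotype at {variant.CHROM}:{variant.POS}; "
                "fill or drop missing calls before loading"
            )
        columns.append(np.where(gt == 0, 0.0, np.where(gt == 1, 0.5, 1.0)))
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if not columns:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix(samples, snp_ids, np.column_stack(columns))


def load_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from CSV (rows = genotypes, header = SNP ids)
    or VCF (biallelic sites, GT field). Format inferred from the suffix
    when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "csv"
    if format == "csv":
        return _load_csv(path)
    if format == "vcf":
        return _load_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


@dataclass(frozen=True)
class SNPPanel:
    """An ordered SNP selection used as predictor input."""

    snp_ids: tuple[str, ...]
    kind: str  # targeted | random | augmented
    n_targeted: int
    n_random: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("targeted", "random", "augmented"):
            raise ValueError(f"unknown panel kind {self.kind!r}")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in panel")
        if len(self.snp_ids) != self.n_targeted + self.n_random:
            raise ValueError("panel size must equal n_targeted + n_random")
        if self.kind == "targeted" and self.n_random != 0:
            raise ValueError("targeted panel cannot contain random SNPs")
        if self.kind == "random" and self.n_targeted != 0:
            raise ValueError("random panel cannot contain targeted SNPs")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.snp_ids) + "\n")

    @staticmethod
    def read_ids(path: str | Path) -> list[str]:
        return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def select_panel(
    matrix: GenotypeMatrix,
    kind: str,
    n_total: int | None = None,
    targeted_ids: list[str] | None = None,
    seed: int = 0,
    exclude_ids: list[str] | None = None,
) -> SNPPanel:
    """Build a targeted, random, or augmented SNP panel from a matrix.

    Random draws are uniform without replacement and deterministic in
    ``seed``; ``exclude_ids`` optionally removes SNPs (e.g. known causal
    ones) from the random pool.
    """
    all_ids = matrix.snp_ids
    if kind in ("targeted", "augmented"):
        if not targeted_ids:
            raise ValueError(f"{kind} panel needs targeted_ids")
        matrix._snp_indices(list(targeted_ids))  # raises if any absent
    if kind == "targeted":
        return SNPPanel(tuple(targeted_ids), "targeted", len(targeted_ids), 0, seed)

    if n_total is None:
        raise ValueError(f"{kind} panel needs n_total")
    if n_total > len(all_ids):
        raise ValueError(f"n_total={n_total} exceeds {len(all_ids)} available SNPs")

    pool = set(all_ids)
    if exclude_ids:
        pool -= set(exclude_ids)
    rng = np.random.default_rng(seed)
    if kind == "random":
        pool_list = sorted(pool)
        if n_total > len(pool_list):
            raise ValueError("random pool smaller than n_total")
        chosen = rng.choice(len(pool_list), size=n_total, replace=False)
        return SNPPanel(
            tuple(pool_list[i] for i in sorted(chosen)), "random", 0, n_total, seed
        )
    if kind == "augmented":
        core = list(targeted_ids)
        if n_total < len(core):
            raise ValueError(
                f"n_total={n_total} smaller than the {len(core)} targeted SNPs"
            )
        fill_pool = sorted(pool - set(core))
        n_fill = n_total - len(core)
        if n_fill > len(fill_pool):
            raise ValueError("not enough non-targeted SNPs to fill the panel")
        chosen = rng.choice(len(fill_pool), size=n_fill, replace=False)
        ids = tuple(core) + tuple(fill_pool[i] for i in sorted(chosen))
        return SNPPanel(ids, "augmented", len(core), n_fill, seed)
    raise ValueError(f"unknown panel kind {kind!r}")
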