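"""Pool-seq allele counts → filtered, imputed allele-frequency matrix.

Pool sequencing estimates population allele frequencies from read counts over
a pool of individuals. Frequencies are unreliable at very low coverage and at
coverage above the haploid pool size (more reads than chromosomes sampled
signals mapping artefacts), so such cells are masked before a fixed chain of
population- and locus-level filters and a per-locus median imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PoolCounts",
    "FrequencyMatrix",
    "FilterReport",
    "read_sync",
    "write_sync",
    "counts_to_freqs",
    "filter_chain",
]

_BASES = ("A", "T", "C", "G")  # sync column order is A:T:C:G:N:del
_ALT_TIE_ORDER = ("A", "C", "G", "T")


@dataclass
class PoolCounts:
    """Reference-allele read counts and coverages per population.

    ``loci`` is indexed by locus id with columns chrom, pos (1-based), ref,
    alt. ``ref_counts`` and ``coverage`` are loci x populations integer
    frames; ``coverage`` is the biallelic coverage (ref + alt reads).
    ``haploid_pool_size`` is 2 x the number of diploid individuals pooled.
    """

    loci: pd.DataFrame
    ref_counts: pd.DataFrame
    coverage: pd.DataFrame
    haploid_pool_size: pd.Series

    def __post_init__(self) -> None:
        if self.loci.index.has_duplicates:
            dup = self.loci.index[self.loci.index.duplicated()][0]
            raise ValueError(f"duplicate locus id {dup!r}")
        if (self.haploid_pool_size <= 0).any():
            bad = self.haploid_pool_size.index[self.haploid_pool_size <= 0][0]
            raise ValueError(f"non-positive pool size for population {bad!r}")
        over = self.ref_counts.to_numpy() > self.coverage.to_numpy()
        if over.any():
            i, j = np.argwhere(over)[0]
            raise ValueError(
                f"ref count exceeds coverage at locus "
                f"{self.ref_counts.index[i]!r}, population "
                f"{self.ref_counts.columns[j]!r}"
            )

    @property
    def populations(self) -> list:
        return list(self.ref_counts.columns)


@dataclass
class FrequencyMatrix:
    """Populations x loci reference-allele frequencies in [0, 1].

    ``freqs`` may contain NaN (missing); ``imputed`` flags entries filled by
    the filter chain rather than observed from reads.
    """

    freqs: pd.DataFrame
    imputed: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.freqs.index, columns=self.freqs.columns
            )
        vals = self.freqs.to_numpy()
        observed = vals[~np.isnan(vals)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def populations(self) -> list:
        return list(self.freqs.index)

    @property
    def loci(self) -> list:
        return list(self.freqs.columns)

    def to_csv(self, path) -> None:
        # rows = loci "chrom:pos"-style ids, columns = population ids
        self.freqs.T.to_csv(path, index_label="locus")

    @classmethod
    def from_csv(cls, path) -> "FrequencyMatrix":
        df = pd.read_csv(path, index_col="locus")
        return cls(freqs=df.T)


@dataclass
class FilterReport:
    """Counts removed at each stage of the filter chain."""

    loci_all_missing: int = 0
    populations_dropped: int = 0
    populations_removed: list = field(default_factory=list)
    loci_too_missing: int = 0
    values_imputed: int = 0
    loci_monomorphic: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def read_sync(path, pop_names, pool_size_diploid, min_rc: int = 0,
              min_pool_size: int = 0) -> PoolCounts:
    """Read popoolation2-style ``.sync`` counts.

    Columns: chrom, pos, ref base, then per pool ``A:T:C:G:N:del``. The
    reference count is the count of the stated ref base; the alt allele is
    the most frequent non-ref base summed across pools (ties broken
    A<C<G<T); coverage = ref + alt reads (N/del columns are ignored, i.e.
    indel-bearing reads are dropped). ``min_rc`` optionally drops loci whose
    overall minor-allele read support is below the threshold.
    ``min_pool_size`` drops populations with fewer diploid individuals.
    """
    pop_names = list(pop_names)
    if np.isscalar(pool_size_diploid):
        sizes = pd.Series(int(pool_size_diploid), index=pop_names)
    else:
        sizes = pd.Series(pool_size_diploid, index=pop_names).astype(int)
    keep_pops = [p for p in pop_names if sizes[p] >= min_pool_size]
    if not keep_pops:
        raise ValueError("min_pool_size removed every population")

    chroms, poss, refs, alts = [], [], [], []
    ref_rows, cov_rows = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 + len(pop_names):
                raise ValueError(
                    f"line {line_no}: expected {3 + len(pop_names)} columns, "
                    f"got {len(parts)}"
                )
            chrom, pos, ref = parts[0], int(parts[1]), parts[2].upper()
            counts = np.zeros((len(pop_names), 4), dtype=np.int64)
            for k, cell in enumerate(parts[3:]):
                fields = cell.split(":")
                counts[k, :] = [int(v) for v in fields[:4]]
            keep_idx = [pop_names.index(p) for p in keep_pops]
            counts = counts[keep_idx]
            if ref not in _BASES:
                raise ValueError(f"line {line_no}: bad ref base {ref!r}")
            ref_col = _BASES.index(ref)
            totals = counts.sum(axis=0)
            alt_candidates = [b for b in _ALT_TIE_ORDER if b != ref]
            alt = max(alt_candidates,
                      key=lambda b: (totals[_BASES.index(b)],
                                     -_ALT_TIE_ORDER.index(b)))
            alt_col = _BASES.index(alt)
            if min_rc > 0:
                minor = min(totals[ref_col], totals[alt_col])
                if minor < min_rc:
                    continue
            chroms.append(chrom)
            poss.append(pos)
            refs.append(ref)
            alts.append(alt)
            ref_rows.append(counts[:, ref_col])
            cov_rows.append(counts[:, ref_col] + counts[:, alt_col])

    ids = pd.Index([f"{c}:{p}" for c, p in zip(chroms, poss)], name="locus")
    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs,
                         "alt": alts}, index=ids)
    return PoolCounts(
        loci=loci,
        ref_counts=pd.DataFrame(np.array(ref_rows, dtype=np.int64).reshape(
            len(ids), len(keep_pops)), index=ids, columns=keep_pops),
        coverage=pd.DataFrame(np.array(cov_rows, dtype=np.int64).reshape(
            len(ids), len(keep_pops)), index=ids, columns=keep_pops),
        haploid_pool_size=(2 * sizes[keep_pops]),
    )


def write_sync(counts: PoolCounts, path) -> None:
    """Write counts in the ``.sync`` dialect (alt reads on the alt base)."""
    base_idx = {b: i for i, b in enumerate(_BASES)}
    with open(path, "w") as fh:
        for lid, row in counts.loci.iterrows():
            ref_c = counts.ref_counts.loc[lid]
            cov = counts.coverage.loc[lid]
            cells = []
            for pop in counts.populations:
                col = [0, 0, 0, 0, 0, 0]
                col[base_idx[row["ref"]]] = int(ref_c[pop])
                col[base_idx[row["alt"]]] = int(cov[pop] - ref_c[pop])
                cells.append(":".join(str(v) for v in col))
            fh.write("\t".join([row["chrom"], str(row["pos"]), row["ref"]]
                               + cells) + "\n")


def counts_to_freqs(counts: PoolCounts, min_cov: int = 3) -> FrequencyMatrix:
    """Reference-allele frequencies with a coverage validity mask.

    frequency = ref/coverage where ``min_cov <= coverage <= haploid pool
    size`` of that population; cells outside the window are missing (NaN).
    No locus is dropped at this stage.
    """
    cov = counts.coverage.to_numpy(dtype=float)
    ref = counts.ref_counts.to_numpy(dtype=float)
    haploid = counts.haploid_pool_size.loc[counts.populations].to_numpy()
    ok = (cov >= min_cov) & (cov <= haploid[np.newaxis, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(ok, ref / cov, np.nan)
    freqs = pd.DataFrame(freq.T, index=counts.ref_counts.columns,
                         columns=counts.ref_counts.index)
    return FrequencyMatrix(freqs=freqs)


def filter_chain(fm: FrequencyMatrix, pop_missing_max: float = 0.70,
                 locus_missing_max_pops: int = 1):
    """Run the fixed filter chain on a masked frequency matrix.

    Stages, in order:

    1. drop loci missing in ALL populations;
    2. drop populations whose missing fraction is >= ``pop_missing_max``;
    3. drop loci missing in more than ``locus_missing_max_pops`` populations;
    4. impute remaining missing values with the per-locus median of observed
       frequencies;
    5. drop loci monomorphic after imputation.

    Returns ``(FrequencyMatrix, FilterReport)``. Idempotent: re-running on
    the output changes nothing.
    """
    freqs = fm.freqs.copy()
    if freqs.shape[0] < 2 or freqs.shape[1] < 1:
        raise ValueError("need at least 2 populations and 1 locus")
    report = FilterReport()

    # stage 1: loci with no observations at all
    all_missing = freqs.isna().all(axis=0)
    report.loci_all_missing = int(all_missing.sum())
    freqs = freqs.loc[:, ~all_missing]

    # stage 2: populations with too much missing data
    if freqs.shape[1] > 0:
        miss_frac = freqs.isna().mean(axis=1)
    else:
        miss_frac = pd.Series(0.0, index=freqs.index)
    drop_pops = miss_frac[miss_frac >= pop_missing_max].index
    report.populations_dropped = len(drop_pops)
    report.populations_removed = list(drop_pops)
    freqs = freqs.drop(index=drop_pops)
    if freqs.shape[0] == 0:
        raise ValueError(
            f"all populations removed at the missingness stage: {report}"
        )

    # stage 3: loci missing in too many of the remaining populations
    n_missing = freqs.isna().sum(axis=0)
    too_missing = n_missing > locus_missing_max_pops
    report.loci_too_missing = int(too_missing.sum())
    freqs = freqs.loc[:, ~too_missing]

    # stage 4: per-locus median imputation
    missing_mask = freqs.isna()
    report.values_imputed = int(missing_mask.to_numpy().sum())
    medians = freqs.median(axis=0, skipna=True)
    freqs = freqs.fillna(medians)

    # stage 5: loci monomorphic after imputation
    mono = freqs.nunique(axis=0) < 2
    report.loci_monomorphic = int(mono.sum())
    freqs = freqs.loc[:, ~mono]
    missing_mask = missing_mask.loc[:, ~mono]

    imputed = fm.imputed.reindex(index=freqs.index, columns=freqs.columns,
                                 fill_value=False) | missing_mask
    return FrequencyMatrix(freqs=freqs, imputed=imputed), report
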