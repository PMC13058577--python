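"""GO-term enrichment of candidate SNPs against the genome-wide background.

Candidate SNPs (from any genotype–environment association method) are mapped
to the coding sequences containing them; the GO annotations of those CDS are
then tested term by term with an exact two-sided binomial test, using the
genome-wide term frequency as the null proportion. Enrichment and depletion
are both reported; p-values are Benjamini–Hochberg adjusted within each
ontology (biological process / molecular function / cellular component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = ["AnnotationCatalog", "load_catalog", "map_snps_to_cds",
           "binomial_enrichment", "enrich_candidates"]

ONTOLOGIES = ("biological_process", "molecular_function",
              "cellular_component")


@dataclass
class AnnotationCatalog:
    """CDS intervals plus their GO annotations.

    ``cds`` is indexed by CDS id with columns chrom, start, end (1-based
    inclusive), strand. ``go`` maps ontology -> DataFrame(cds_id, term).
    ``genome_counts`` holds per-ontology term-annotation counts over all
    annotated CDS.
    """

    cds: pd.DataFrame
    go: dict
    genome_counts: dict = field(default_factory=dict)
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        bad = self.cds[self.cds["start"] > self.cds["end"]]
        if len(bad):
            raise ValueError(
                f"malformed CDS interval (start > end): {bad.index[0]!r}")
        if not self.genome_counts:
            self.genome_counts = {
                ont: df["term"].value_counts().to_dict()
                for ont, df in self.go.items()
            }
        for ont, df in self.go.items():
            counts = df["term"].value_counts().to_dict()
            if counts != self.genome_counts.get(ont):
                raise ValueError(
                    f"genome_counts for {ont!r} disagree with the annotation "
                    "multimap")
        if not self._trees:
            for chrom, sub in self.cds.groupby("chrom"):
                tree = IntervalTree()
                for cid, row in sub.iterrows():
                    # intervaltree is half-open; +1 makes 'end' inclusive
                    tree.addi(int(row["start"]), int(row["end"]) + 1, cid)
                self._trees[chrom] = tree


def load_catalog(gff3_path, go_tsv_path) -> AnnotationCatalog:
    """Build a catalog from a GFF3 (CDS features) and a CDS→GO TSV.

    The TSV needs columns ``cds_id``, ``go_id``, ``ontology`` (ontology
    values matching biological_process / molecular_function /
    cellular_component).
    """
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    rows = {}
    for feat in db.features_of_type("CDS"):
        cid = feat.attributes.get("ID", [feat.id])[0]
        if feat.start > feat.end:
            raise ValueError(f"malformed CDS interval (start > end): {cid!r}")
        if cid in rows:  # multi-exon CDS: keep the spanning interval
            rows[cid]["start"] = min(rows[cid]["start"], feat.start)
            rows[cid]["end"] = max(rows[cid]["end"], feat.end)
        else:
            rows[cid] = {"chrom": feat.seqid, "start": feat.start,
                         "end": feat.end, "strand": feat.strand}
    cds = pd.DataFrame.from_dict(rows, orient="index")
    cds.index.name = "cds_id"

    table = pd.read_csv(go_tsv_path, sep="\t")
    required = {"cds_id", "go_id", "ontology"}
    if missing := required - set(table.columns):
        raise ValueError(f"GO table missing columns {sorted(missing)}")
    go = {}
    for ont, sub in table.groupby("ontology"):
        if ont not in ONTOLOGIES:
            raise ValueError(f"unknown ontology {ont!r}")
        go[ont] = pd.DataFrame({"cds_id": sub["cds_id"].to_numpy(),
                                "term": sub["go_id"].to_numpy()})
    return AnnotationCatalog(cds=cds, go=go)


def map_snps_to_cds(loci: pd.DataFrame, catalog: AnnotationCatalog) -> set:
    """CDS ids whose 1-based inclusive interval contains a candidate SNP.

    ``loci`` needs columns ``chrom`` and ``pos``; strand is ignored and a
    CDS hit by several SNPs counts once.
    """
    hits = set()
    for _, row in loci.iterrows():
        tree = catalog._trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in tree.at(int(row["pos"])):
            hits.add(iv.data)
    return hits


def _term_counts(catalog: AnnotationCatalog, cds_ids: set) -> dict:
    out = {}
    for ont, df in catalog.go.items():
        sub = df[df["cds_id"].isin(cds_ids)]
        out[ont] = sub["term"].value_counts().to_dict()
    return out


def binomial_enrichment(candidate_counts: dict, candidate_total: int,
                        genome_counts: dict, genome_total: int,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Exact two-sided binomial enrichment for one ontology.

    For term g with genome proportion ``p0 = genome_counts[g] /
    genome_total``, the p-value is the exact two-sided (minimum-likelihood)
    binomial probability of the observed candidate count out of
    ``candidate_total``. Direction is 'enriched' when the observed
    proportion exceeds p0, 'depleted' when below, 'neutral' at equality.
    Returns a frame with p, BH-adjusted q, direction and a significance flag
    at ``alpha``.
    """
    if candidate_total <= 0 or genome_total <= 0:
        raise ValueError("totals must be positive")
    for term, cnt in candidate_counts.items():
        if term not in genome_counts:
            raise ValueError(
                f"term {term!r} present in candidates but absent from the "
                "genome background (inconsistent catalog)")
        if cnt > genome_counts[term]:
            raise ValueError(
                f"candidate count exceeds genome count for term {term!r}")
    rows = []
    for term, g_count in sorted(genome_counts.items()):
        observed = int(candidate_counts.get(term, 0))
        p0 = g_count / genome_total
        p = stats.binomtest(observed, candidate_total, p0,
                            alternative="two-sided").pvalue
        obs_prop = observed / candidate_total
        if obs_prop > p0:
            direction = "enriched"
        elif obs_prop < p0:
            direction = "depleted"
        else:
            direction = "neutral"
        rows.append({"term": term, "observed": observed,
                     "candidate_total": candidate_total,
                     "genome_count": g_count, "genome_total": genome_total,
                     "p0": p0, "pvalue": float(p), "direction": direction})
    out = pd.DataFrame(rows).set_index("term")
    out["qvalue"] = stats.false_discovery_control(out["pvalue"], method="bh")
    out["significant"] = out["qvalue"] < alpha
    return out


def enrich_candidates(catalog: AnnotationCatalog, candidate_cds: set,
                      alpha: float = 0.05) -> dict:
    """Per-ontology enrichment tables for a candidate CDS set."""
    cand = _term_counts(catalog, candidate_cds)
    results = {}
    for ont, df in catalog.go.items():
        genome_counts = catalog.genome_counts[ont]
        genome_total = int(sum(genome_counts.values()))
        cand_counts = cand.get(ont, {})
        cand_total = int(sum(cand_counts.values()))
        if cand_total == 0:
            results[ont] = pd.DataFrame()
            continue
        results[ont] = binomial_enrichment(cand_counts, cand_total,
                                           genome_counts, genome_total,
                                           alpha=alpha)
    return results
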