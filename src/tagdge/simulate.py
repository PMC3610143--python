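"""Synthetic data for every pipeline stage, with a full truth ledger.

The generator emulates the two-library DGE design: a transcriptome with
a controlled number of NlaIII (CATG) sites per gene, two tag libraries of
unequal sequencing depth drawn from a shared log-normal abundance vector
with a planted set of fold-changed genes, per-base substitution error,
and adaptor / low-quality contamination at stated fractions.  Everything
a pipeline summary can report (clean totals, mapping rates, differential
calls, enrichment positives) has a known expected value derivable from
the truth ledger.

Defaults mirror the scale *ratios* of a real two-breed experiment, not
its magnitudes: the deeper library holds 200,000 tags and the shallower
126,000 (depth ratio ~0.63), over 2,000 genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import SENSE, TranscriptRecord, build_reference_library
from .tags import RawTagSet, TagRead

#: Synthetic 21-nt adaptor used for contamination reads (not a vendor sequence).
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

_SPACER_BASES = np.array(list("ACT"))   # no G: spacers can never contain CATG
_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Planted parameters of a two-library simulation."""

    abundance: dict[str, float]          # shared base relative frequencies
    log2_effects: dict[str, float]       # planted fold changes (log2, A vs B)
    n_a: int
    n_b: int
    error_rate: float
    adaptor_fraction: float
    lowq_fraction: float
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"abundances must sum to 1 (got {total})")
        stray = set(self.log2_effects) - set(self.abundance)
        if stray:
            raise ValueError(f"fold-change genes outside gene set: {sorted(stray)[:5]}")

    def library_abundances(self) -> tuple[dict[str, float], dict[str, float]]:
        """Per-library abundances: half the log2 effect up in A, half down
        in B, renormalized."""
        a = {g: w * 2.0 ** (self.log2_effects.get(g, 0.0) / 2.0)
             for g, w in self.abundance.items()}
        b = {g: w * 2.0 ** (-self.log2_effects.get(g, 0.0) / 2.0)
             for g, w in self.abundance.items()}
        sa, sb = sum(a.values()), sum(b.values())
        return {g: w / sa for g, w in a.items()}, {g: w / sb for g, w in b.items()}

    def ledger_frame(self) -> pd.DataFrame:
        """Per-gene truth: abundances, effects, expected tag counts."""
        ab_a, ab_b = self.library_abundances()
        tag_frac = 1.0 - self.adaptor_fraction - self.lowq_fraction
        rows = []
        for g in sorted(self.abundance):
            rows.append({
                "gene_id": g,
                "base_abundance": self.abundance[g],
                "log2_effect": self.log2_effects.get(g, 0.0),
                "planted": g in self.log2_effects,
                "expected_count_a": ab_a[g] * self.n_a * tag_frac,
                "expected_count_b": ab_b[g] * self.n_b * tag_frac,
            })
        return pd.DataFrame(rows)


def _random_tag(rng: np.random.Generator) -> str:
    """CATG + 17 nt whose interior re-creates no CATG."""
    while True:
        tail = "".join(rng.choice(_BASES, size=17))
        tag = "CATG" + tail
        if "CATG" not in tag[1:]:
            return tag


def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (400, 1200),
    catg_sites_per_gene_range: tuple[int, int] = (1, 4),
    seed: int = 0,
    shared_tag_fraction: float = 0.0,
    source: str = "synthetic",
    priority: int = 1,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Random transcripts with an exact, known CATG site layout.

    Spacer segments are drawn from {A, C, T} so the only sense-strand CATG
    occurrences are the planted ones; every planted site carries a full
    17 nt downstream, so sense digestion yields exactly the planted tags
    and the 3'-most planted tag has position rank 1.  With
    ``shared_tag_fraction`` > 0, that fraction of genes reuses the rank-1
    tag of another gene, planting reference-library ambiguity.
    """
    lo_l, hi_l = length_range
    lo_s, hi_s = catg_sites_per_gene_range
    if lo_l < 1 or lo_s < 1:
        raise ValueError("ranges must be positive")
    if lo_l < 21 * hi_s:
        raise ValueError(
            f"length_range too short for {hi_s} tag sites ({21 * hi_s} nt needed)"
        )
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    meta_rows = []
    for i in range(n_genes):
        gene = f"G{i:05d}"
        length = int(rng.integers(lo_l, hi_l + 1))
        n_sites = int(rng.integers(lo_s, hi_s + 1))
        tags = [_random_tag(rng) for _ in range(n_sites)]
        spacer_total = length - 21 * n_sites
        cuts = np.sort(rng.integers(0, spacer_total + 1, size=n_sites))
        spacer_lens = np.diff(np.concatenate([[0], cuts, [spacer_total]]))
        parts = []
        for j, tag in enumerate(tags):
            parts.append("".join(rng.choice(_SPACER_BASES, size=spacer_lens[j])))
            parts.append(tag)
        parts.append("".join(rng.choice(_SPACER_BASES, size=spacer_lens[-1])))
        seq = "".join(parts)
        records.append(TranscriptRecord(gene, source, priority, seq))
        meta_rows.append({
            "gene_id": gene, "length": len(seq), "n_sites": n_sites,
            "rank1_tag": tags[-1], "tags": ",".join(tags),
        })
    meta = pd.DataFrame(meta_rows)

    if shared_tag_fraction > 0 and n_genes >= 2:
        n_shared = int(round(shared_tag_fraction * n_genes))
        victims = rng.choice(n_genes, size=min(n_shared, n_genes // 2),
                             replace=False)
        for v in victims:
            donor = int(rng.integers(0, n_genes))
            if donor == v:
                donor = (donor + 1) % n_genes
            donor_tag = meta.loc[donor, "rank1_tag"]
            rec = records[v]
            old_tag = meta.loc[v, "rank1_tag"]
            pos = rec.sequence.rindex(old_tag)
            new_seq = (rec.sequence[:pos] + donor_tag
                       + rec.sequence[pos + 21:])
            records[v] = TranscriptRecord(rec.gene_id, rec.source,
                                          rec.priority, new_seq)
            meta.loc[v, "rank1_tag"] = donor_tag
            old_list = meta.loc[v, "tags"].split(",")
            old_list[-1] = donor_tag
            meta.loc[v, "tags"] = ",".join(old_list)
    return records, meta


def make_truth(
    genes: list[str],
    seed: int = 0,
    n_a: int = 126_000,
    n_b: int = 200_000,
    n_planted: int = 200,
    planted_log2fc: float = 3.0,
    min_expected_count: float = 25.0,
    abundance_sigma: float = 1.5,
    error_rate: float = 0.001,
    adaptor_fraction: float = 0.01,
    lowq_fraction: float = 0.01,
) -> SyntheticTruth:
    """Log-normal abundances with planted symmetric fold changes.

    Planted genes are drawn only from genes abundant enough that the
    expected tag count in both libraries exceeds ``min_expected_count``
    even on the down-regulated side, so recovery is a property of the
    test, not of sampling noise at vanishing counts.  Effects alternate
    in sign (half up, half down in A).
    """
    rng = np.random.default_rng(seed)
    w = np.exp(abundance_sigma * rng.standard_normal(len(genes)))
    w /= w.sum()
    abundance = dict(zip(genes, w.astype(float)))
    tag_frac = 1.0 - adaptor_fraction - lowq_fraction
    worst_depth = min(n_a, n_b) * tag_frac * 2.0 ** (-abs(planted_log2fc) / 2.0)
    eligible = [g for g in genes
                if abundance[g] * worst_depth >= min_expected_count]
    if len(eligible) < n_planted:
        raise ValueError(
            f"only {len(eligible)} genes meet the minimum expected count; "
            f"cannot plant {n_planted} fold changes"
        )
    planted = rng.choice(eligible, size=n_planted, replace=False)
    effects = {g: (planted_log2fc if i % 2 == 0 else -planted_log2fc)
               for i, g in enumerate(planted)}
    return SyntheticTruth(abundance, effects, n_a, n_b, error_rate,
                          adaptor_fraction, lowq_fraction, seed)


def _mutate(tag: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(tag)))
    base = tag[pos]
    alternatives = [b for b in "ACGT" if b != base]
    return tag[:pos] + alternatives[int(rng.integers(0, 3))] + tag[pos + 1:]


def _simulate_one_library(
    n_reads: int,
    abundances: dict[str, float],
    gene_tags: dict[str, str],
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> RawTagSet:
    genes = sorted(abundances)
    n_adaptor = rng.binomial(n_reads, truth.adaptor_fraction)
    n_lowq = rng.binomial(n_reads - n_adaptor,
                          truth.lowq_fraction / (1.0 - truth.adaptor_fraction))
    n_tags = n_reads - n_adaptor - n_lowq
    probs = np.array([abundances[g] for g in genes])
    counts = rng.multinomial(n_tags, probs)
    p_read_error = 1.0 - (1.0 - truth.error_rate) ** 21
    reads: list[TagRead] = []
    for g, c in zip(genes, counts):
        if c == 0:
            continue
        tag = gene_tags[g]
        n_err = rng.binomial(c, p_read_error) if truth.error_rate > 0 else 0
        reads.extend([TagRead(tag)] * (c - n_err))
        reads.extend(TagRead(_mutate(tag, rng)) for _ in range(n_err))
    reads.extend([TagRead(DEFAULT_ADAPTOR)] * n_adaptor)
    for _ in range(n_lowq):
        g = genes[int(rng.integers(0, len(genes)))]
        tag = gene_tags[g]
        pos = int(rng.integers(0, 21))
        reads.append(TagRead(tag[:pos] + "N" + tag[pos + 1:]))
    order = rng.permutation(len(reads))
    return RawTagSet([reads[i] for i in order])


def simulate_libraries(
    truth: SyntheticTruth,
    meta: pd.DataFrame,
) -> tuple[RawTagSet, RawTagSet, pd.DataFrame]:
    """Draw the two raw tag libraries defined by a truth object.

    Tags are sampled from each gene's rank-1 sense tag (the 3'-most site,
    as the bead-capture protocol dictates) with per-base substitution
    error; adaptor and N-containing reads are mixed in at the planted
    fractions.  Returns the libraries and the per-gene truth ledger.
    """
    gene_tags = dict(zip(meta["gene_id"], meta["rank1_tag"]))
    missing = set(truth.abundance) - set(gene_tags)
    if missing:
        raise ValueError(f"abundance genes missing from transcriptome: "
                         f"{sorted(missing)[:5]}")
    rng = np.random.default_rng(truth.seed)
    ab_a, ab_b = truth.library_abundances()
    lib_a = _simulate_one_library(truth.n_a, ab_a, gene_tags, truth, rng)
    lib_b = _simulate_one_library(truth.n_b, ab_b, gene_tags, truth, rng)
    return lib_a, lib_b, truth.ledger_frame()


def generate_annotations(
    genes: list[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 100),
    enriched_term: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random term->gene memberships, optionally with one loaded term.

    ``enriched_term`` is a dict with keys ``term_id``, ``de_genes`` (the
    planted positives), ``odds_ratio`` and ``baseline`` (membership
    probability of a non-DE gene); membership of DE genes is drawn at the
    probability whose odds are ``odds_ratio`` times the baseline odds, so
    an odds ratio of 1 reduces to a plain random term.
    """
    lo, hi = term_size_range
    if lo < 1 or hi > len(genes):
        raise ValueError("term sizes infeasible for the gene set")
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        rows.extend({"term_id": f"T{t:04d}", "gene_id": g} for g in members)
    if enriched_term is not None:
        de = set(enriched_term["de_genes"])
        p0 = float(enriched_term.get("baseline", 0.05))
        odds = enriched_term["odds_ratio"] * p0 / (1.0 - p0)
        p1 = odds / (1.0 + odds)
        tid = enriched_term.get("term_id", "T_ENRICHED")
        for g in genes:
            p = p1 if g in de else p0
            if rng.random() < p:
                rows.append({"term_id": tid, "gene_id": g})
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def generate_ct_table(
    target_ratios: dict[str, float],
    reference_gene: str = "RPS20",
    group_a: str = "A",
    group_b: str = "B",
    n_biological: int = 3,
    n_technical: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic long-format Ct table with known expression ratios.

    ``target_ratios`` maps each target gene to its true group_a / group_b
    expression ratio; the planted ddCt is -log2(ratio).  Gaussian noise of
    ``noise_sd`` cycles is added per technical replicate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in (group_a, group_b):
        for s in range(n_biological):
            sample = f"{group}{s + 1}"
            ref_ct = 20.0 + rng.normal(0, 0.3)
            for rep in range(n_technical):
                rows.append({"sample_id": sample, "group": group,
                             "gene_id": reference_gene, "replicate": rep + 1,
                             "ct": ref_ct + rng.normal(0, noise_sd)})
            for gene, ratio in target_ratios.items():
                base_dct = 4.0
                dct = base_dct - (math.log2(ratio) if group == group_a else 0.0)
                for rep in range(n_technical):
                    rows.append({"sample_id": sample, "group": group,
                                 "gene_id": gene, "replicate": rep + 1,
                                 "ct": ref_ct + dct + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id",
                                       "replicate", "ct"])
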