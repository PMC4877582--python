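"""Synthetic study generator: toy genome, grouped expression, gene sets.

Emulates the design of a three-group bulk RNA-seq study of nasal mucosa
(an eosinophilic disease group, a noneosinophilic disease group and
controls, 3 samples each): interleaved protein-coding and noncoding loci
on a toy genome, log-normal FPKM with planted differential expression, and
planted high-correlation lncRNA-mRNA neighbor pairs.  Every generated
transcript carries ground truth (class, novelty, DE pattern, pair
membership), so catalog construction, differential expression, target
prediction and enrichment can all be scored against known answers.

Construction is deliberately constructive rather than rejection-sampled:
lncRNA loci are *placed* to realise their planted positional class
(intergenic with a controlled gap; inside one intron of a coding host;
overlapping a coding exon on the opposite strand), and "known" lncRNAs
are copied into the reference annotation with jittered termini but an
identical intron chain.

Noise model: per-transcript log2-FPKM baselines are normal (lncRNA
baseline drawn lower than mRNA baseline, as seen in tissue RNA-seq), group
effects are additive log2 shifts, and fragment counts are Poisson around
the expectation implied by inverting the FPKM formula.  A log-normal/
Poisson hierarchy was chosen over a negative binomial for transparency at
n = 3 per group; the per-sample dispersion is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GenomicInterval, TranscriptModel, write_gtf
from .expression import ExpressionMatrix

__all__ = [
    "PlantedPair",
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_expression",
    "simulate_gene_sets",
    "write_inputs",
    "COMPARISONS",
]

#: The three pairwise comparisons of the study design, in reporting order.
COMPARISONS = (
    ("eosinophilic", "control"),
    ("noneosinophilic", "control"),
    ("eosinophilic", "noneosinophilic"),
)


@dataclass(frozen=True)
class PlantedPair:
    """A planted lncRNA-mRNA cis neighbor pair.

    rho: target Pearson correlation of the pair's log-scale noise.
    de_log2fc: additional log2 up-shift of BOTH members in the eosinophilic
        group (0 leaves the pair free of group structure, so its observed
        correlation estimates rho alone).
    """

    rho: float = 0.9
    de_log2fc: float = 0.0


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the study conditions.

    Counts of lncRNA loci per (positional class, novelty) mirror the mix of
    a tissue catalog: mostly novel lincRNAs, a minority of intronic and
    antisense models, and a small known fraction.
    """

    seed: int = 1
    n_chromosomes: int = 2
    n_coding_loci: int = 60
    n_lincrna_novel: int = 20
    n_lincrna_known: int = 6
    n_intronic_novel: int = 8
    n_intronic_known: int = 2
    n_antisense_novel: int = 8
    n_antisense_known: int = 4
    second_isoform_prob: float = 0.3
    groups: tuple[str, str, str] = ("eosinophilic", "noneosinophilic", "control")
    n_samples_per_group: int = 3
    de_fraction: float = 0.12
    effect_size: float = 3.0  # log2 shift of planted DE transcripts
    mrna_log2_mean: float = 4.0
    lnc_log2_mean: float = 2.0
    between_sd: float = 1.5  # spread of per-transcript baselines (log2)
    within_sd: float = 0.4  # per-sample biological noise (log2)
    pair_log2_mean: float = 5.0  # baseline of planted-pair members
    total_fragments: float = 2e7
    total_jitter_sd: float = 0.05  # lognormal jitter of per-sample totals
    cis_window: int = 100_000
    planted_pairs: tuple[PlantedPair, ...] = (
        PlantedPair(rho=0.9, de_log2fc=6.0),  # headline pair: correlated AND disease-specific
        PlantedPair(rho=0.9, de_log2fc=0.0),  # quiet pair: correlation only
    )

    @property
    def n_lnc(self) -> int:
        return (
            self.n_lincrna_novel
            + self.n_lincrna_known
            + self.n_intronic_novel
            + self.n_intronic_known
            + self.n_antisense_novel
            + self.n_antisense_known
        )

    def validate(self) -> None:
        n_hosted = (
            self.n_intronic_novel
            + self.n_intronic_known
            + self.n_antisense_novel
            + self.n_antisense_known
        )
        if n_hosted > self.n_coding_loci:
            raise ValueError(
                f"{n_hosted} hosted lncRNA loci need distinct coding hosts but "
                f"only {self.n_coding_loci} coding loci are configured"
            )
        if len(self.planted_pairs) > min(
            self.n_lincrna_novel, self.n_coding_loci // self.n_chromosomes
        ):
            raise ValueError("more planted pairs than available lincRNA/coding slots")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Per-transcript truth plus the planted pair list.

    ``transcripts`` is indexed by transcript_id with columns: locus_id,
    chrom, kind (mRNA/lncRNA), lnc_class, novelty, length, de_pattern
    (none/eos/noneos/common), de_direction (+1/-1/0), coding_score, pair_id.
    """

    transcripts: pd.DataFrame
    planted_pairs: list[dict]

    def de_direction(self, group_a: str, group_b: str) -> pd.Series:
        """True DE direction (+1 up in a, -1 down in a, 0 null) per transcript."""
        pat = self.transcripts["de_pattern"]
        d = self.transcripts["de_direction"]
        key = (group_a, group_b)
        if key == ("eosinophilic", "control"):
            return d.where(pat.isin(["eos", "common"]), 0)
        if key == ("noneosinophilic", "control"):
            return d.where(pat.isin(["noneos", "common"]), 0)
        if key == ("eosinophilic", "noneosinophilic"):
            out = pd.Series(0, index=self.transcripts.index)
            out[pat == "eos"] = d[pat == "eos"]
            out[pat == "noneos"] = -d[pat == "noneos"]
            return out
        raise ValueError(f"unknown comparison: {group_a} vs {group_b}")

    def to_tsv(self, path: str | Path) -> None:
        self.transcripts.to_csv(path, sep="\t", index_label="transcript_id")


def _make_coding_locus(
    rng: np.random.Generator, chrom: str, start: int, locus_id: str, two_isoforms: bool
) -> tuple[list[TranscriptModel], int]:
    """Lay one coding gene at ``start``; returns (isoforms, end of span)."""
    n_exons = int(rng.integers(5, 10))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for _ in range(n_exons):
        elen = int(rng.integers(120, 300))
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(1500, 4000))
    pos = exons[-1][1]
    iso1 = TranscriptModel(
        f"{locus_id}.1",
        locus_id,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype="protein_coding",
    )
    isoforms = [iso1]
    if two_isoforms:
        skip = int(rng.integers(1, n_exons - 1))
        kept = [x for i, x in enumerate(exons) if i != skip]
        isoforms.append(
            TranscriptModel(
                f"{locus_id}.2",
                locus_id,
                tuple(GenomicInterval(chrom, s, e, strand) for s, e in kept),
                biotype="protein_coding",
            )
        )
    return isoforms, pos


def _make_lincrna(
    rng: np.random.Generator, chrom: str, start: int, tid: str, locus_id: str,
    n_exons: int,
) -> tuple[TranscriptModel, int]:
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for _ in range(n_exons):
        elen = int(rng.integers(250, 800))
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(400, 2000))
    pos = exons[-1][1]
    return (
        TranscriptModel(
            tid,
            locus_id,
            tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
            biotype="lncRNA_candidate",
        ),
        pos,
    )


def _make_intronic(
    rng: np.random.Generator, host: TranscriptModel, tid: str, locus_id: str,
    single_exon: bool,
) -> TranscriptModel:
    """Place a lncRNA wholly inside one intron of the host's first isoform."""
    introns = [i for i in host.introns if len(i) >= 700]
    intron = introns[int(rng.integers(0, len(introns)))]
    strand = "+" if rng.random() < 0.5 else "-"
    anchor = intron.start + 60
    if single_exon:
        exons = [(anchor, anchor + 420)]
    else:
        exons = [(anchor, anchor + 160), (anchor + 360, anchor + 520)]
    return TranscriptModel(
        tid,
        locus_id,
        tuple(GenomicInterval(host.chrom, s, e, strand) for s, e in exons),
        biotype="lncRNA_candidate",
    )


def _make_antisense(
    rng: np.random.Generator, host: TranscriptModel, tid: str, locus_id: str
) -> TranscriptModel:
    """Two exons on the opposite strand, one overlapping an internal host exon."""
    k = int(rng.integers(1, host.n_exons - 1))
    e = host.exons[k]
    strand = "-" if host.strand == "+" else "+"
    exons = [(e.start - 450, e.start - 300), (e.start - 100, e.start + 100)]
    return TranscriptModel(
        tid,
        locus_id,
        tuple(GenomicInterval(host.chrom, s, e_, strand) for s, e_ in exons),
        biotype="lncRNA_candidate",
    )


def _jittered_reference(
    rng: np.random.Generator, t: TranscriptModel, ref_id: str
) -> TranscriptModel:
    """Reference copy of a known lncRNA: same intron chain, jittered termini.

    Single-exon copies keep >= 50 % reciprocal overlap of the shorter model.
    """
    exons = [(e.start, e.end) for e in t.exons]
    if len(exons) == 1:
        s, e = exons[0]
        shift = int(rng.integers(0, max(1, (e - s) // 5)))
        exons = [(s + shift, e + shift)]
    else:
        exons[0] = (max(0, exons[0][0] - int(rng.integers(0, 40))), exons[0][1])
        exons[-1] = (exons[-1][0], exons[-1][1] + int(rng.integers(0, 40)))
    return TranscriptModel(
        ref_id,
        f"ref_{t.locus_id}",
        tuple(GenomicInterval(t.chrom, s, e, t.strand) for s, e in exons),
        biotype="lncRNA_known",
    )


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[AnnotationSet, AnnotationSet, AnnotationSet, GroundTruth]:
    """Generate (assembled, coding reference, lncRNA reference, ground truth).

    The assembled set contains every coding isoform and every lncRNA; the
    lncRNA reference contains jittered copies of the "known" lncRNAs only.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 101])
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # --- chromosome block plans: interleave coding and lincRNA loci -------
    coding_ids = [f"CG{i:04d}" for i in range(cfg.n_coding_loci)]
    linc_specs = [("lincRNA", "novel")] * cfg.n_lincrna_novel + [
        ("lincRNA", "known")
    ] * cfg.n_lincrna_known
    linc_ids = [f"XLOC_L{i:04d}" for i in range(len(linc_specs))]

    n_pairs = len(cfg.planted_pairs)
    per_chrom_blocks: dict[str, list[tuple[str, object]]] = {c: [] for c in chroms}
    # planted pairs first, on chr1: coding locus immediately followed by its lincRNA
    for p in range(n_pairs):
        per_chrom_blocks[chroms[0]].append(("coding", coding_ids[p]))
        per_chrom_blocks[chroms[0]].append(("linc_paired", p))
    coding_rest = coding_ids[n_pairs:]
    linc_rest = list(range(n_pairs, len(linc_specs)))
    for i, cid in enumerate(coding_rest):
        per_chrom_blocks[chroms[i % len(chroms)]].append(("coding", cid))
    for i, li in enumerate(linc_rest):
        per_chrom_blocks[chroms[i % len(chroms)]].append(("linc", li))
    for c in chroms[1:]:
        rng.shuffle(per_chrom_blocks[c])

    assembled = AnnotationSet()
    coding_ref = AnnotationSet()
    lnc_ref = AnnotationSet()
    rows: list[dict] = []
    coding_first_isoform: dict[str, TranscriptModel] = {}
    linc_transcripts: dict[int, TranscriptModel] = {}
    pair_mrna_locus: dict[int, str] = {}

    for chrom in chroms:
        cursor = 100_000
        prev_coding: str | None = None
        for kind, payload in per_chrom_blocks[chrom]:
            if kind == "linc_paired":
                gap = int(rng.integers(20_000, 80_000))
            elif rng.random() < 0.5:
                gap = int(rng.integers(10_000, 90_000))
            else:
                gap = int(rng.integers(150_000, 250_000))
            start = cursor + gap
            if kind == "coding":
                cid = payload
                two = rng.random() < cfg.second_isoform_prob and cid not in coding_ids[:n_pairs]
                isoforms, end = _make_coding_locus(rng, chrom, start, cid, two)
                for iso in isoforms:
                    assembled.add(iso)
                    coding_ref.add(
                        TranscriptModel(
                            f"ref_{iso.transcript_id}", iso.locus_id, iso.exons,
                            biotype="protein_coding",
                        )
                    )
                coding_first_isoform[cid] = isoforms[0]
                prev_coding = cid
                cursor = end
            else:
                li = payload if kind == "linc" else None
                if kind == "linc_paired":
                    li = payload  # pair index doubles as lincRNA index
                    pair_mrna_locus[payload] = prev_coding
                cls, novelty = linc_specs[li]
                n_exons = (
                    int(rng.integers(2, 4))
                    if novelty == "novel"
                    else int(rng.integers(1, 4))
                )
                tid = linc_ids[li]
                t, end = _make_lincrna(rng, chrom, start, tid, f"loc_{tid}", n_exons)
                assembled.add(t)
                linc_transcripts[li] = t
                cursor = end

    # --- hosted lncRNAs: intronic and antisense, distinct coding hosts ----
    hosted_specs = (
        [("intronic", "novel")] * cfg.n_intronic_novel
        + [("intronic", "known")] * cfg.n_intronic_known
        + [("antisense", "novel")] * cfg.n_antisense_novel
        + [("antisense", "known")] * cfg.n_antisense_known
    )
    # avoid the paired loci so planted-pair expression stays single-isoform clean
    host_pool = [c for c in coding_ids if c not in coding_ids[:n_pairs]]
    hosts = rng.choice(len(host_pool), size=len(hosted_specs), replace=False)
    hosted_transcripts: list[tuple[TranscriptModel, str, str]] = []
    for (cls, novelty), hi in zip(hosted_specs, hosts):
        host = coding_first_isoform[host_pool[int(hi)]]
        i = len(hosted_transcripts)
        tid = f"XLOC_H{i:04d}"
        if cls == "intronic":
            t = _make_intronic(rng, host, tid, f"loc_{tid}", single_exon=(novelty == "known"))
        else:
            t = _make_antisense(rng, host, tid, f"loc_{tid}")
        assembled.add(t)
        hosted_transcripts.append((t, cls, novelty))

    # --- reference lncRNA annotation: jittered copies of the known models -
    known_models = [
        (linc_transcripts[li], linc_specs[li][0]) for li in range(len(linc_specs))
        if linc_specs[li][1] == "known"
    ] + [(t, cls) for t, cls, novelty in hosted_transcripts if novelty == "known"]
    for j, (t, _cls) in enumerate(known_models):
        lnc_ref.add(_jittered_reference(rng, t, f"LNCREF{j:04d}"))

    # --- ground-truth rows and coding-potential scores --------------------
    def add_row(t: TranscriptModel, kind: str, lnc_class: str, novelty: str) -> None:
        if kind == "mRNA":
            score = float(np.maximum(rng.normal(200.0, 80.0), 10.0))
        else:
            score = float(np.minimum(rng.normal(-25.0, 10.0), -0.5))
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "locus_id": t.locus_id,
                "chrom": t.chrom,
                "kind": kind,
                "lnc_class": lnc_class,
                "novelty": novelty,
                "length": t.length,
                "coding_score": score,
                "de_pattern": "none",
                "de_direction": 0,
                "pair_id": "",
            }
        )

    for t in assembled:
        if t.biotype == "protein_coding":
            add_row(t, "mRNA", "", "")
    for li, t in linc_transcripts.items():
        add_row(t, "lncRNA", linc_specs[li][0], linc_specs[li][1])
    for t, cls, novelty in hosted_transcripts:
        add_row(t, "lncRNA", cls, novelty)

    truth_df = pd.DataFrame(rows).set_index("transcript_id")

    # --- plant DE patterns and pairs --------------------------------------
    rng_de = np.random.default_rng([cfg.seed, 202])
    patterns = np.array(["eos", "noneos", "common"])
    for tid in truth_df.index:
        if rng_de.random() < cfg.de_fraction:
            truth_df.loc[tid, "de_pattern"] = str(
                rng_de.choice(patterns, p=[0.4, 0.3, 0.3])
            )
            truth_df.loc[tid, "de_direction"] = int(
                1 if rng_de.random() < 0.5 else -1
            )

    planted = []
    for p, spec in enumerate(cfg.planted_pairs):
        lnc_id = linc_ids[p]
        mrna_locus = pair_mrna_locus[p]
        mrna_tid = coding_first_isoform[mrna_locus].transcript_id
        pid = f"pair{p}"
        for tid in (lnc_id, mrna_tid):
            truth_df.loc[tid, "pair_id"] = pid
            if spec.de_log2fc > 0:
                truth_df.loc[tid, "de_pattern"] = "eos"
                truth_df.loc[tid, "de_direction"] = 1
            else:
                truth_df.loc[tid, "de_pattern"] = "none"
                truth_df.loc[tid, "de_direction"] = 0
        planted.append(
            {
                "pair_id": pid,
                "lncrna_id": lnc_id,
                "mrna_locus": mrna_locus,
                "mrna_transcript": mrna_tid,
                "rho": spec.rho,
                "de_log2fc": spec.de_log2fc,
            }
        )

    return assembled, coding_ref, lnc_ref, GroundTruth(truth_df, planted)


def simulate_expression(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, dict[str, float], dict[str, int]]:
    """Fragment-count matrix plus per-sample totals and transcript lengths.

    log2 FPKM = baseline + group shift + noise; planted-pair noise is drawn
    from a bivariate normal with the configured correlation; counts are
    Poisson around the expectation implied by inverting the FPKM formula.
    """
    rng = np.random.default_rng([cfg.seed, 303])
    df = truth.transcripts
    tids = list(df.index)
    n_t = len(tids)
    samples = [
        f"{g}_{i + 1}" for g in cfg.groups for i in range(cfg.n_samples_per_group)
    ]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    n_s = len(samples)

    base_mu = np.where(
        df["kind"].to_numpy() == "mRNA", cfg.mrna_log2_mean, cfg.lnc_log2_mean
    )
    mu = base_mu + rng.normal(0.0, cfg.between_sd, size=n_t)

    pos = {t: i for i, t in enumerate(tids)}
    for pair in truth.planted_pairs:
        mu[pos[pair["lncrna_id"]]] = cfg.pair_log2_mean
        mu[pos[pair["mrna_transcript"]]] = cfg.pair_log2_mean

    shift = np.zeros((n_t, n_s))
    pat = df["de_pattern"].to_numpy()
    direction = df["de_direction"].to_numpy().astype(float)
    eff = np.where(
        df["pair_id"].to_numpy() != "",
        [
            next(
                (p["de_log2fc"] for p in truth.planted_pairs if p["pair_id"] == pid),
                0.0,
            )
            for pid in df["pair_id"]
        ],
        cfg.effect_size,
    )
    group_of = np.array([groups[s] for s in samples])
    in_eos = group_of == "eosinophilic"
    in_noneos = group_of == "noneosinophilic"
    shift += np.outer(np.where(np.isin(pat, ["eos", "common"]), direction * eff, 0.0), in_eos)
    shift += np.outer(np.where(np.isin(pat, ["noneos", "common"]), direction * eff, 0.0), in_noneos)

    eps = rng.normal(0.0, cfg.within_sd, size=(n_t, n_s))
    for pair in truth.planted_pairs:
        i, j = pos[pair["lncrna_id"]], pos[pair["mrna_transcript"]]
        rho = pair["rho"]
        z1 = rng.normal(size=n_s)
        z2 = rng.normal(size=n_s)
        eps[i] = cfg.within_sd * z1
        eps[j] = cfg.within_sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    log2_fpkm = mu[:, None] + shift + eps
    fpkm = np.power(2.0, log2_fpkm)

    totals = {
        s: float(cfg.total_fragments * np.exp(rng.normal(0.0, cfg.total_jitter_sd)))
        for s in samples
    }
    lengths = {t: int(df.loc[t, "length"]) for t in tids}
    lam = fpkm * np.array([lengths[t] for t in tids])[:, None] * np.array(
        [totals[s] for s in samples]
    )[None, :] / 1e9
    counts = rng.poisson(lam).astype(float)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=tids, columns=samples), groups, unit="fragments"
    )
    return matrix, totals, lengths


def simulate_gene_sets(
    truth: GroundTruth,
    n_terms: int = 25,
    n_enriched: int = 3,
    de_overlap_frac: float = 0.6,
    term_size: tuple[int, int] = (10, 40),
    seed: int = 1,
) -> dict[str, list[str]]:
    """Gene sets over coding loci; ``n_enriched`` terms over-sample true-DE loci.

    DE loci are those with a transcript truly shifted in the eosinophilic
    vs control comparison, so enrichment of that comparison's DE genes has
    known positives.
    """
    rng = np.random.default_rng([seed, 404])
    df = truth.transcripts
    coding = df[df["kind"] == "mRNA"]
    background = sorted(coding["locus_id"].unique())
    de_dir = truth.de_direction("eosinophilic", "control")
    de_loci = sorted(coding.loc[de_dir.loc[coding.index] != 0, "locus_id"].unique())
    non_de = [g for g in background if g not in set(de_loci)]
    out: dict[str, list[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        size = min(size, len(background))
        if i < n_enriched and de_loci:
            n_from_de = min(int(round(size * de_overlap_frac)), len(de_loci))
            pick_de = rng.choice(len(de_loci), size=n_from_de, replace=False)
            n_rest = min(size - n_from_de, len(non_de))
            pick_bg = rng.choice(len(non_de), size=n_rest, replace=False)
            genes = [de_loci[j] for j in pick_de] + [non_de[j] for j in pick_bg]
        else:
            pick = rng.choice(len(background), size=size, replace=False)
            genes = [background[j] for j in pick]
        out[f"TERM{i:03d}"] = sorted(genes)
    return out


def write_inputs(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate one full study and write every pipeline input file.

    Emits assembled/coding/lncRNA-reference GTFs, fragment counts, totals,
    lengths, sample groups, coding scores, gene sets (GMT) and the ground
    truth table.  Returns the path of each file by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembled, coding_ref, lnc_ref, truth = simulate_annotation(cfg)
    counts, totals, lengths = simulate_expression(cfg, truth)
    gene_sets = simulate_gene_sets(truth, seed=cfg.seed)

    paths = {
        "assembled_gtf": outdir / "assembled.gtf",
        "coding_gtf": outdir / "coding_ref.gtf",
        "lnc_ref_gtf": outdir / "lncrna_ref.gtf",
        "counts_tsv": outdir / "counts.tsv",
        "totals_tsv": outdir / "totals.tsv",
        "lengths_tsv": outdir / "lengths.tsv",
        "groups_tsv": outdir / "groups.tsv",
        "scores_tsv": outdir / "coding_scores.tsv",
        "gene_sets_gmt": outdir / "gene_sets.gmt",
        "ground_truth_tsv": outdir / "ground_truth.tsv",
    }
    write_gtf(assembled, paths["assembled_gtf"])
    write_gtf(coding_ref, paths["coding_gtf"])
    write_gtf(lnc_ref, paths["lnc_ref_gtf"])
    counts.to_tsv(paths["counts_tsv"])
    pd.DataFrame(
        {"sample_id": list(totals), "total_fragments": list(totals.values())}
    ).to_csv(paths["totals_tsv"], sep="\t", index=False)
    pd.DataFrame(
        {"transcript_id": list(lengths), "length": list(lengths.values())}
    ).to_csv(paths["lengths_tsv"], sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": counts.samples, "group": [counts.sample_groups[s] for s in counts.samples]}
    ).to_csv(paths["groups_tsv"], sep="\t", index=False)
    truth.transcripts["coding_score"].rename_axis("transcript_id").reset_index().to_csv(
        paths["scores_tsv"], sep="\t", index=False
    )
    from .targets import write_gmt

    write_gmt(gene_sets, paths["gene_sets_gmt"])
    truth.to_tsv(paths["ground_truth_tsv"])
    return paths
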