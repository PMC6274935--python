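"""Synthetic data with known ground truth for every pipeline input.

Two generators are provided:

* :func:`generate_ct_table` emulates a two-group TaqMan-card qPCR study:
  per-miRNA planted log2 fold changes (one PCR cycle = one log2 unit),
  Gaussian noise in Ct space (between-sample and between-replicate), shared
  per-sample offsets that the reference-miRNA normalization must cancel, and
  censoring of reactions above the detection cutoff.

* :func:`generate_interaction_databases` emulates the interaction-database
  exports consumed by the network stages: five predictor tables, a validated
  table with an evidence column, TF -> miRNA and TF -> gene edge tables —
  with an exact, brute-force-verified list of the planted regulatory motifs
  (FBLs and the three FFL kinds) plus decoy edges that are rejection-sampled
  so they never complete an unplanted motif.

Defaults mirror the emulated study: 58 case vs 20 control samples, a
13-miRNA panel in which six miRNAs carry the observed log2 fold changes and
seven are null, two endogenous reference miRNAs, and triplicate wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import MotifInstance
from .targets import PairSet, consensus_filter, merge_validated_predicted

__all__ = [
    "DEFAULT_PANEL",
    "DEFAULT_REFERENCES",
    "ExprSimConfig",
    "NetSimConfig",
    "NetSimResult",
    "generate_ct_table",
    "generate_interaction_databases",
    "result_pair_set",
]

#: The emulated 13-miRNA panel: six miRNAs with their observed log2 fold
#: changes and seven with no case/control effect.
DEFAULT_PANEL: tuple[tuple[str, float], ...] = (
    ("miR-320a", 0.8383653),
    ("miR-125a-5p", 0.9214846),
    ("miR-652-3p", 0.5953385),
    ("miR-185-5p", 0.5878233),
    ("miR-942-5p", 0.7367637),
    ("miR-25-3p", 0.5819802),
    ("let-7a-5p", 0.0),
    ("let-7b-5p", 0.0),
    ("miR-221-3p", 0.0),
    ("miR-182-5p", 0.0),
    ("miR-181a-5p", 0.0),
    ("miR-99b-5p", 0.0),
    ("miR-148b-3p", 0.0),
)

DEFAULT_REFERENCES: tuple[str, ...] = ("miR-191-5p", "miR-103a-3p")

PREDICTOR_NAMES = ("miranda", "rna22", "mirdb", "targetscan", "microt")
_TF_MIRNA_SOURCES = ("CHEA", "ENCODE", "TRANSFAC", "MotifMap", "JASPAR", "TransmiR")
_CONSENSUS_MIN = 4  # survival threshold applied downstream

_PRED_COLUMNS = {  # per-predictor export dialects (see targets.DIALECTS)
    "miranda": ("mirna", "gene_symbol"),
    "rna22": ("miRNA", "Gene"),
    "mirdb": ("miRNA Name", "Gene Symbol"),
    "targetscan": ("miRNA", "Gene Symbol"),
    "microt": ("mirna", "gene"),
}


class ConfigurationError(ValueError):
    """Invalid or infeasible simulation configuration."""


# =====================================================================
# Expression (Ct table) generator
# =====================================================================

@dataclass
class ExprSimConfig:
    """Two-group qPCR simulation parameters (all Ct quantities in cycles)."""

    n_case: int = 58
    n_control: int = 20
    mirnas: tuple[tuple[str, float], ...] = DEFAULT_PANEL
    references: tuple[str, ...] = DEFAULT_REFERENCES
    base_ct: float = 28.0
    replicate_sd: float = 0.25
    sample_sd: float = 1.0
    dropout_ct: float = 40.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigurationError("Need at least 2 samples per group")
        if self.replicate_sd < 0 or self.sample_sd < 0:
            raise ConfigurationError("Noise SDs must be non-negative")
        names = [m for m, _ in self.mirnas]
        if len(set(names)) != len(names):
            raise ConfigurationError("Duplicate miRNA names in the panel")
        clash = set(self.references) & set(names)
        if clash:
            raise ConfigurationError(
                f"Reference miRNA(s) also listed as targets: {sorted(clash)}"
            )


def generate_ct_table(config: ExprSimConfig) -> pd.DataFrame:
    """Long-format Ct table with one row per (sample, miRNA, replicate).

    Case-group Ct of miRNA m is lowered by its planted log2 fold change (in
    cycles) relative to control. Each miRNA gets a stable abundance offset;
    each sample a shared technical offset (applied to references too, so dCt
    cancels it). Ct values above ``dropout_ct`` are emitted as missing
    (the undetected sentinel in the CSV writer). Output is bit-identical for
    a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    panel = list(config.mirnas) + [(r, 0.0) for r in config.references]
    offsets = rng.uniform(-3.0, 4.0, size=len(panel))
    samples = [(f"case{i + 1:02d}", "case") for i in range(config.n_case)] + [
        (f"control{i + 1:02d}", "control") for i in range(config.n_control)
    ]
    rows = []
    for sample, group in samples:
        s_off = rng.normal(0.0, config.sample_sd) if config.sample_sd > 0 else 0.0
        for (mirna, lfc), m_off in zip(panel, offsets):
            mu = config.base_ct + m_off + s_off - (lfc if group == "case" else 0.0)
            for rep in range(1, config.n_replicates + 1):
                ct = mu + (
                    rng.normal(0.0, config.replicate_sd)
                    if config.replicate_sd > 0
                    else 0.0
                )
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "mirna": mirna,
                        "replicate": rep,
                        "ct": np.nan if ct > config.dropout_ct else ct,
                    }
                )
    return pd.DataFrame(rows)


# =====================================================================
# Interaction-database generator
# =====================================================================

@dataclass
class NetSimConfig:
    """Regulatory-network simulation parameters.

    ``planted`` gives the number of standalone FBLs and of each FFL kind to
    plant on disjoint node sets (every composite FFL necessarily contributes
    its reciprocal TF/miRNA pair to the FBL truth as well).
    ``consensus_coverage`` is the distribution of predictor-support counts
    assigned to planted miRNA-target edges; ``support_overrides`` pins
    (mirna, target) pairs to an explicit (n_predictors, validated) so that
    under-supported pairs — and the motifs that need them — drop out of the
    post-filter truth.
    """

    n_tf: int = 12
    n_mirna: int = 10
    n_gene: int = 30
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "fbl": 2, "mirna_ffl": 3, "tf_ffl": 4, "composite_ffl": 1
        }
    )
    decoy_edges: int = 40
    n_predictors: int = 5
    consensus_coverage: dict[int, float] = field(
        default_factory=lambda: {4: 0.5, 5: 0.5}
    )
    validated_fraction: float = 0.3
    support_overrides: dict[tuple[str, str], tuple[int, bool]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self):
        p = self.planted
        for k in ("fbl", "mirna_ffl", "tf_ffl", "composite_ffl"):
            p.setdefault(k, 0)
            if p[k] < 0:
                raise ConfigurationError(f"Negative planted count for {k}")
        n_motifs = sum(p.values())
        n_ffl = p["mirna_ffl"] + p["tf_ffl"] + p["composite_ffl"]
        if self.n_tf < n_motifs or self.n_mirna < n_motifs or self.n_gene < n_ffl:
            raise ConfigurationError(
                f"Planted counts infeasible: need {n_motifs} TFs and miRNAs "
                f"and {n_ffl} genes, have {self.n_tf}/{self.n_mirna}/{self.n_gene}"
            )
        if self.n_predictors < 1:
            raise ConfigurationError("Need at least one predictor source")
        if any(k < 0 or k > self.n_predictors for k in self.consensus_coverage):
            raise ConfigurationError("consensus_coverage keys out of range")


@dataclass
class NetSimResult:
    """Generated database exports plus exact motif ground truth.

    ``truth`` is the post-consensus-filter motif list (brute-force verified);
    ``planted`` records the instances as planted, before any support-based
    drop-out. ``de_mirnas`` are the miRNA ids to feed to graph assembly.
    """

    predictions: dict[str, pd.DataFrame]
    validated: pd.DataFrame
    tf_mirna: pd.DataFrame
    tf_gene: pd.DataFrame
    truth: list[MotifInstance]
    planted: list[MotifInstance]
    de_mirnas: list[str]

    def truth_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in ("FBL", "miRNA-FFL", "TF-FFL", "composite-FFL")}
        for inst in self.truth:
            counts[inst.kind] += 1
        return counts

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.predictions.items():
            df.to_csv(out / f"pred_{name}.tsv", sep="\t", index=False)
        self.validated.to_csv(out / "validated.tsv", sep="\t", index=False)
        self.tf_mirna.to_csv(out / "tf_mirna.tsv", sep="\t", index=False)
        self.tf_gene.to_csv(out / "tf_gene.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "kind": i.kind,
                    "tf": i.tf,
                    "mirna": i.mirna,
                    "gene": i.gene or "",
                }
                for i in self.truth
            ]
        ).to_csv(out / "truth_motifs.tsv", sep="\t", index=False)


def _brute_force_motifs(tfs, mirnas, e_tm, s_mt, e_tg, s_mg) -> list[MotifInstance]:
    """Exhaustive pair/triple scan over explicit edge sets (the oracle the
    generator checks itself against; independent of the graph machinery)."""
    out = []
    for t in tfs:
        for m in mirnas:
            t2m = (t, m) in e_tm
            m2t = (m, t) in s_mt
            if t2m and m2t:
                out.append(MotifInstance("FBL", tf=t, mirna=m))
            if not (t2m or m2t):
                continue
            for x in sorted({x for (tt, x) in e_tg if tt == t}):
                if (m, x) not in s_mg or x in (t, m):
                    continue
                if t2m and m2t:
                    kind = "composite-FFL"
                elif t2m:
                    kind = "TF-FFL"
                else:
                    kind = "miRNA-FFL"
                out.append(MotifInstance(kind, tf=t, mirna=m, gene=x))
    return sorted(out, key=lambda i: (i.kind, i.tf, i.mirna, i.gene or ""))


def generate_interaction_databases(config: NetSimConfig) -> NetSimResult:
    """Generate predictor/validated/TF edge tables with exact motif ground truth.

    Motifs are planted on disjoint node sets (so planted edges cannot combine
    into unintended motifs); every planted miRNA-target edge receives enough
    predictor support or a reporter-assay validation to survive the downstream
    consensus filter, unless overridden. Decoy edges are rejection-sampled so
    that no decoy completes a motif in the post-filter graph. The emitted
    truth list is recomputed by exhaustive brute force over the final edge
    sets and verified on every draw.
    """
    rng = np.random.default_rng(config.seed)
    tfs = [f"TF{i + 1}" for i in range(config.n_tf)]
    mirnas = [f"miR-s{i + 1}" for i in range(config.n_mirna)]
    genes = [f"G{i + 1}" for i in range(config.n_gene)]

    tf_pool = list(rng.permutation(tfs))
    mir_pool = list(rng.permutation(mirnas))
    gene_pool = list(rng.permutation(genes))

    e_tm: set[tuple[str, str]] = set()   # TF -> miRNA
    e_tg: set[tuple[str, str]] = set()   # TF -> gene
    pair_raw: dict[tuple[str, str], bool] = {}  # miRNA -> target (target may be a TF)
    planted: list[MotifInstance] = []

    def plant_pair(m: str, target: str) -> None:
        pair_raw.setdefault((m, target), True)  # True: planted (needs support)

    for _ in range(config.planted["fbl"]):
        t, m = tf_pool.pop(), mir_pool.pop()
        e_tm.add((t, m))
        plant_pair(m, t)
        planted.append(MotifInstance("FBL", tf=t, mirna=m))
    for _ in range(config.planted["mirna_ffl"]):
        t, m, x = tf_pool.pop(), mir_pool.pop(), gene_pool.pop()
        plant_pair(m, t)
        e_tg.add((t, x))
        plant_pair(m, x)
        planted.append(MotifInstance("miRNA-FFL", tf=t, mirna=m, gene=x))
    for _ in range(config.planted["tf_ffl"]):
        t, m, x = tf_pool.pop(), mir_pool.pop(), gene_pool.pop()
        e_tm.add((t, m))
        e_tg.add((t, x))
        plant_pair(m, x)
        planted.append(MotifInstance("TF-FFL", tf=t, mirna=m, gene=x))
    for _ in range(config.planted["composite_ffl"]):
        t, m, x = tf_pool.pop(), mir_pool.pop(), gene_pool.pop()
        e_tm.add((t, m))
        plant_pair(m, t)
        e_tg.add((t, x))
        plant_pair(m, x)
        planted.append(MotifInstance("composite-FFL", tf=t, mirna=m, gene=x))

    # -- predictor support for planted miRNA-target edges ---------------
    cov_keys = sorted(config.consensus_coverage)
    cov_p = np.array([config.consensus_coverage[k] for k in cov_keys], dtype=float)
    cov_p /= cov_p.sum()

    support: dict[tuple[str, str], tuple[int, bool]] = {}
    for pair in sorted(pair_raw):
        if pair in config.support_overrides:
            support[pair] = config.support_overrides[pair]
            continue
        k = int(rng.choice(cov_keys, p=cov_p))
        validated = bool(rng.random() < config.validated_fraction)
        if k < _CONSENSUS_MIN and not validated:
            validated = True  # default coverage guarantees survival
        support[pair] = (k, validated)

    def survives(pair: tuple[str, str]) -> bool:
        k, validated = support[pair]
        return k >= _CONSENSUS_MIN or validated

    tf_set, gene_set = set(tfs), set(genes)
    s_mt = {p for p in support if p[1] in tf_set and survives(p)}
    s_mg = {p for p in support if p[1] in gene_set and survives(p)}

    truth = _brute_force_motifs(tfs, mirnas, e_tm, s_mt, e_tg, s_mg)

    # -- decoys (rejection-sampled: must not complete any motif) --------
    def tg_of(t):
        return {x for (tt, x) in e_tg if tt == t}

    def mtargets(m):
        return {x for (mm, x) in s_mg if mm == m}

    def creates_motif(kind: str, a: str, b: str) -> bool:
        if kind == "tm":  # TF a -> miRNA b
            if (b, a) in s_mt:
                return True
            return bool(tg_of(a) & mtargets(b))
        if kind == "tg":  # TF a -> gene b
            for m in mirnas:
                if (m, b) in s_mg and ((a, m) in e_tm or (m, a) in s_mt):
                    return True
            return False
        if kind == "mg":  # miRNA a -> gene b (surviving support)
            for (t, x) in e_tg:
                if x == b and ((t, a) in e_tm or (a, t) in s_mt):
                    return True
            return False
        if kind == "mt":  # miRNA a -> TF b (surviving support)
            if (b, a) in e_tm:
                return True
            return bool(tg_of(b) & mtargets(a))
        raise ValueError(kind)

    weak_pairs: list[tuple[str, str]] = []  # low support, filtered downstream
    kinds = ["tm", "tg", "mg", "mt", "mg_low", "mt_low"]
    kind_p = np.array([0.2, 0.25, 0.25, 0.05, 0.2, 0.05])
    placed, attempts = 0, 0
    max_attempts = 400 * max(config.decoy_edges, 1)
    while placed < config.decoy_edges:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                "Could not place the requested decoy edges without creating motifs"
            )
        kind = str(rng.choice(kinds, p=kind_p))
        if kind == "tm":
            t, m = tfs[rng.integers(len(tfs))], mirnas[rng.integers(len(mirnas))]
            if (t, m) in e_tm or creates_motif("tm", t, m):
                continue
            e_tm.add((t, m))
        elif kind == "tg":
            t, x = tfs[rng.integers(len(tfs))], genes[rng.integers(len(genes))]
            if (t, x) in e_tg or creates_motif("tg", t, x):
                continue
            e_tg.add((t, x))
        elif kind in ("mg", "mg_low"):
            m, x = mirnas[rng.integers(len(mirnas))], genes[rng.integers(len(genes))]
            if (m, x) in support:
                continue
            if kind == "mg":
                if creates_motif("mg", m, x):
                    continue
                k = int(rng.choice(cov_keys, p=cov_p))
                support[(m, x)] = (max(k, _CONSENSUS_MIN), False)
                s_mg.add((m, x))
            else:
                support[(m, x)] = (int(rng.integers(1, _CONSENSUS_MIN)), False)
                weak_pairs.append((m, x))
        else:  # mt / mt_low
            m, t = mirnas[rng.integers(len(mirnas))], tfs[rng.integers(len(tfs))]
            if (m, t) in support:
                continue
            if kind == "mt":
                if creates_motif("mt", m, t):
                    continue
                k = int(rng.choice(cov_keys, p=cov_p))
                support[(m, t)] = (max(k, _CONSENSUS_MIN), False)
                s_mt.add((m, t))
            else:
                support[(m, t)] = (int(rng.integers(1, _CONSENSUS_MIN)), False)
                weak_pairs.append((m, t))
        placed += 1

    # -- generator self-consistency check on every draw -----------------
    final = _brute_force_motifs(tfs, mirnas, e_tm, s_mt, e_tg, s_mg)
    if final != truth:
        raise RuntimeError(
            "Generator self-check failed: decoys altered the motif ground truth"
        )

    # -- materialize the database exports -------------------------------
    pred_names = list(PREDICTOR_NAMES[: config.n_predictors])
    if config.n_predictors > len(PREDICTOR_NAMES):
        pred_names += [
            f"pred{i + 1}"
            for i in range(len(PREDICTOR_NAMES), config.n_predictors)
        ]
    pred_rows: dict[str, list[tuple[str, str]]] = {n: [] for n in pred_names}
    val_rows: list[dict] = []
    for pair in sorted(support):
        k, validated = support[pair]
        m, target = pair
        chosen = rng.choice(pred_names, size=k, replace=False) if k else []
        for name in chosen:
            pred_rows[name].append((m, target))
        if validated:
            val_rows.append(
                {"mirna": m, "gene": target, "evidence": "Luciferase reporter assay"}
            )
    # a few weakly-supported pairs get non-reporter "validation" rows, which
    # the default evidence filter must discard
    for m, target in weak_pairs[: max(2, len(weak_pairs) // 4)]:
        val_rows.append({"mirna": m, "gene": target, "evidence": "Western blot"})

    predictions = {}
    for name in pred_names:
        cols = _PRED_COLUMNS.get(name, ("mirna", "gene"))
        predictions[name] = pd.DataFrame(pred_rows[name], columns=list(cols))
    validated_df = pd.DataFrame(val_rows, columns=["mirna", "gene", "evidence"])

    tm_out = []
    for t, m in sorted(e_tm):
        n_src = int(rng.integers(1, 3))
        for src in rng.choice(_TF_MIRNA_SOURCES, size=n_src, replace=False):
            tm_out.append({"tf": t, "mirna": m, "source": str(src)})
    tf_mirna_df = pd.DataFrame(tm_out, columns=["tf", "mirna", "source"])

    tg_out = [
        {
            "tf": t,
            "gene": x,
            "sign": str(rng.choice(["Activation", "Repression"])),
            "source": "TRRUST",
        }
        for t, x in sorted(e_tg)
    ]
    tf_gene_df = pd.DataFrame(tg_out, columns=["tf", "gene", "sign", "source"])

    return NetSimResult(
        predictions=predictions,
        validated=validated_df,
        tf_mirna=tf_mirna_df,
        tf_gene=tf_gene_df,
        truth=truth,
        planted=planted,
        de_mirnas=mirnas,
    )


def result_pair_set(result: NetSimResult, min_sources: int = _CONSENSUS_MIN) -> PairSet:
    """Run the generated exports through the consensus + validated merge.

    Builds one PairSet per predictor table, applies the >= ``min_sources``
    consensus filter, filters the validated table to reporter-assay evidence,
    and returns the merged union — the same path a user takes with files.
    """
    predicted = []
    for name, df in result.predictions.items():
        ps = PairSet()
        mcol, gcol = df.columns[:2]
        for _, r in df.iterrows():
            ps.add(str(r[mcol]), str(r[gcol]), predictor=name)
        predicted.append(ps)
    consensus = consensus_filter(predicted, min_sources=min_sources)
    validated = PairSet()
    for _, r in result.validated.iterrows():
        if "reporter" not in str(r["evidence"]).lower():
            continue
        validated.add(str(r["mirna"]), str(r["gene"]), validated=True,
                      evidence=str(r["evidence"]))
    union, _ = merge_validated_predicted(validated, consensus)
    return union
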