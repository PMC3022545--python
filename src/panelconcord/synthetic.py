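"""Synthetic two-panel expression study generator.

Emulates a paired-platform design: the same 20 FFPE breast-tumor RNA
samples (9 HER2+, 11 HER2-) hybridized on a dense cancer panel ("1.5K",
three probes per gene) and a whole-genome panel ("24K", one to eight probes
per gene), sharing ~498 genes. The generator plants full ground truth —
per-gene baselines and HER2 group effects, per-probe offsets, subject
effects, a panel-specific intensity bias, match-tier assignments,
sequence-matched probe pairs, and a hub-centred interaction graph — so
every downstream stage can be tested for parameter recovery.

The measurement model on the log2 scale for probe p of gene g in sample s:

    x_pgs = mu_g + beta_g * I[s in HER2+] + b_s + pi_p
            + delta_panel(mu_g) + eta_(s,extract) + eps

with eps ~ N(0, sigma_tech) per measurement and eta a per-gene extract-level
random effect with variance sigma_extract^2 - sigma_tech^2, drawn once per
RNA extract and shared by all of that extract's measurements (and by the
probes of a gene), so technical-replicate differences have SD
sqrt(2)*sigma_tech while extract-replicate differences have
sqrt(2)*sigma_extract at the probe level. Making eta vary by gene rather
than being a whole-array offset keeps the extra extract variance visible
after intensity-dependent normalization, which would absorb any constant
array shift.
Emitted intensities are 2**x (strictly positive). The panel bias
delta(mu) = d_max / (1 + exp(-k (mu - a0))) applies to panel A only: panel A
reads high, with the excess attenuated at low expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ParameterError
from .io_formats import (
    MANIFEST_COLUMNS,
    METADATA_COLUMNS,
    SCALE_INTENSITY,
    ExpressionMatrix,
)

PANEL_A = "1.5K"
PANEL_B = "24K"

_BASES = np.array(list("ACGT"))


def _default_probes_b_dist() -> dict[int, float]:
    # genes per probe-count: 333 with 1 probe, 86 with 2, 64 with 3,
    # 15 spread over 4-6 (split evenly)
    return {1: 333 / 498, 2: 86 / 498, 3: 64 / 498, 4: 5 / 498, 5: 5 / 498, 6: 5 / 498}


@dataclass
class BiasParams:
    """Logistic panel-A-minus-panel-B offset in baseline log2 abundance."""

    d_max: float = 1.0
    k: float = 1.5
    a0: float = 7.5


@dataclass
class SimulationConfig:
    n_genes: int = 498
    probes_per_gene_a: int = 3
    probes_per_gene_b_dist: dict = field(default_factory=_default_probes_b_dist)
    n_pos: int = 9
    n_neg: int = 11
    n_tech_rep: int = 8
    n_extract_rep: int = 8
    n_overlap_rep: int = 4
    sigma_tech_a: float = 0.39
    sigma_tech_b: float = 0.15
    sigma_extract_a: float = 0.49
    sigma_extract_b: float = 0.15
    sigma_probe: float = 0.3
    sigma_bio: float = 0.5
    de_fraction: float = 0.05
    fc_range: tuple = (0.5, 1.2)
    erbb2_fc: float = 1.5
    bias_params: BiasParams = field(default_factory=BiasParams)
    n_seq_matched: int = 17
    alias_fractions: tuple = (27 / 498, 5 / 498)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_hubs: int = 3
    n_distractors: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.bias_params, dict):
            self.bias_params = BiasParams(**self.bias_params)
        if isinstance(self.fc_range, list):
            self.fc_range = tuple(self.fc_range)
        if isinstance(self.alias_fractions, list):
            self.alias_fractions = tuple(self.alias_fractions)
        self.probes_per_gene_b_dist = {
            int(k): float(v) for k, v in self.probes_per_gene_b_dist.items()
        }
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_genes",
            "probes_per_gene_a",
            "n_pos",
            "n_neg",
            "n_tech_rep",
            "n_extract_rep",
            "n_hubs",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_overlap_rep < 0 or self.n_distractors < 0:
            raise ConfigurationError("n_overlap_rep and n_distractors must be >= 0")
        total = sum(self.probes_per_gene_b_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"probes_per_gene_b_dist must sum to 1 (got {total!r})"
            )
        if any(k < 1 for k in self.probes_per_gene_b_dist):
            raise ConfigurationError("probes_per_gene_b_dist keys must be >= 1")
        if self.n_overlap_rep > min(self.n_tech_rep, self.n_extract_rep):
            raise ConfigurationError(
                "n_overlap_rep must not exceed min(n_tech_rep, n_extract_rep)"
            )
        n_subjects = self.n_pos + self.n_neg
        if n_subjects < 4:
            raise ConfigurationError("n_pos + n_neg must be at least 4")
        if self.n_tech_rep > n_subjects or self.n_extract_rep > n_subjects:
            raise ConfigurationError("replicate counts exceed number of subjects")
        if self.n_tech_rep + self.n_extract_rep - self.n_overlap_rep > n_subjects:
            raise ConfigurationError("replicate sets do not fit in the subject pool")
        for name in (
            "sigma_tech_a",
            "sigma_tech_b",
            "sigma_extract_a",
            "sigma_extract_b",
            "sigma_probe",
            "sigma_bio",
            "baseline_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sigma_extract_a < self.sigma_tech_a or self.sigma_extract_b < self.sigma_tech_b:
            raise ConfigurationError(
                "sigma_extract must be >= sigma_tech on each panel"
            )
        if not 0 <= self.de_fraction <= 1:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        lo, hi = self.fc_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("fc_range must satisfy 0 <= lo <= hi")
        if self.n_seq_matched < 0 or self.n_seq_matched > self.n_genes:
            raise ConfigurationError("n_seq_matched must be in [0, n_genes]")
        f2, f3 = self.alias_fractions
        if f2 < 0 or f3 < 0 or f2 + f3 > 1:
            raise ConfigurationError("alias_fractions must be >= 0 and sum to <= 1")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            text = fh.read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Planted ground truth for one simulated study."""

    gene_ids: list  # panel-A gene symbols, the canonical keys
    mu: np.ndarray  # per-gene baseline log2 abundance
    beta: np.ndarray  # per-gene HER2+ minus HER2- log2 effect
    flagship_gene: str
    de_genes: list  # genes with beta != 0, flagship included
    tier: dict  # gene -> 1|2|3
    subjects: pd.DataFrame  # subject_id, group, her2_ihc, b (biological effect)
    probes_a: pd.DataFrame  # probe_id, gene, offset, sequence, position
    probes_b: pd.DataFrame
    seq_matched_pairs: pd.DataFrame  # panelA_probe_id, panelB_probe_id, offset
    hub_genes: list

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length))
    flat = _BASES[codes]
    return ["".join(row) for row in flat]


def _centered_offsets(rng: np.random.Generator, counts: np.ndarray, sigma: float) -> np.ndarray:
    """Per-probe offsets, mean-centered within each gene (probe effects are contrasts)."""
    out = []
    for c in counts:
        o = rng.normal(0.0, sigma, size=c)
        out.append(o - o.mean())
    return np.concatenate(out) if out else np.empty(0)


def generate_truth(config: SimulationConfig) -> TruthSet:
    """Draw the full planted ground truth; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 11])

    n = config.n_genes
    gene_ids = [f"GENE{i + 1:04d}" for i in range(n)]
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    flagship = gene_ids[0]
    beta = np.zeros(n)
    beta[0] = config.erbb2_fc
    n_de = round(config.de_fraction * n)
    others = rng.choice(np.arange(1, n), size=min(n_de, n - 1), replace=False)
    lo, hi = config.fc_range
    beta[others] = rng.uniform(lo, hi, size=others.size) * rng.choice([-1.0, 1.0], size=others.size)
    de_genes = [flagship] + [gene_ids[i] for i in sorted(others)]

    n_t2 = round(config.alias_fractions[0] * n)
    n_t3 = round(config.alias_fractions[1] * n)
    special = rng.choice(np.arange(n), size=n_t2 + n_t3, replace=False)
    tier = {g: 1 for g in gene_ids}
    for i in special[:n_t2]:
        tier[gene_ids[i]] = 2
    for i in special[n_t2:]:
        tier[gene_ids[i]] = 3

    # subjects: interleave groups so replicate subjects span HER2+/HER2-
    labels = []
    pos_left, neg_left = config.n_pos, config.n_neg
    while pos_left or neg_left:
        if pos_left:
            labels.append("HER2+")
            pos_left -= 1
        if neg_left:
            labels.append("HER2-")
            neg_left -= 1
    ihc = []
    pos_seen = neg_seen = 0
    for lab in labels:
        if lab == "HER2+":
            ihc.append("2+" if pos_seen < 2 else "3+")
            pos_seen += 1
        else:
            ihc.append("0" if neg_seen % 2 == 0 else "1+")
            neg_seen += 1
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:02d}" for i in range(len(labels))],
            "group": labels,
            "her2_ihc": ihc,
            "b": rng.normal(0.0, config.sigma_bio, size=len(labels)),
        }
    )

    counts_a = np.full(n, config.probes_per_gene_a)
    ks = np.array(sorted(config.probes_per_gene_b_dist))
    probs = np.array([config.probes_per_gene_b_dist[k] for k in ks], dtype=float)
    counts_b = rng.choice(ks, size=n, p=probs / probs.sum())

    def _probe_table(panel: str, counts: np.ndarray, seq_len: int) -> pd.DataFrame:
        prefix = "PA" if panel == PANEL_A else "PB"
        ids, genes = [], []
        for gi, c in enumerate(counts):
            for k in range(c):
                ids.append(f"{prefix}_{gi + 1:04d}_{k + 1}")
                genes.append(gene_ids[gi])
        df = pd.DataFrame(
            {
                "probe_id": ids,
                "gene": genes,
                "sequence": _random_seqs(rng, len(ids), seq_len),
                "position": rng.integers(1, 4000, size=len(ids)),
            }
        )
        df["offset"] = _centered_offsets(rng, counts, config.sigma_probe)
        return df

    probes_a = _probe_table(PANEL_A, counts_a, 22)
    probes_b = _probe_table(PANEL_B, counts_b, 50)

    # embed the first panel-A probe of n_seq_matched genes inside the
    # first panel-B probe of the same gene
    match_genes_idx = rng.choice(np.arange(n), size=config.n_seq_matched, replace=False)
    pairs = []
    for gi in sorted(match_genes_idx):
        pa = probes_a[probes_a["gene"] == gene_ids[gi]].iloc[0]
        pb_mask = probes_b["gene"] == gene_ids[gi]
        pb_idx = probes_b.index[pb_mask][0]
        pb_seq = probes_b.at[pb_idx, "sequence"]
        off = int(rng.integers(0, len(pb_seq) - len(pa["sequence"]) + 1))
        new_seq = pb_seq[: off] + pa["sequence"] + pb_seq[off + len(pa["sequence"]) :]
        probes_b.at[pb_idx, "sequence"] = new_seq
        pairs.append(
            {
                "panelA_probe_id": pa["probe_id"],
                "panelB_probe_id": probes_b.at[pb_idx, "probe_id"],
                "offset": off,
            }
        )
    seq_pairs = pd.DataFrame(pairs, columns=["panelA_probe_id", "panelB_probe_id", "offset"])

    hubs = [f"HUB{i + 1}" for i in range(config.n_hubs)]
    return TruthSet(
        gene_ids=gene_ids,
        mu=mu,
        beta=beta,
        flagship_gene=flagship,
        de_genes=de_genes,
        tier=tier,
        subjects=subjects,
        probes_a=probes_a,
        probes_b=probes_b,
        seq_matched_pairs=seq_pairs,
        hub_genes=hubs,
    )


def _panel_bias(mu: np.ndarray, bp: BiasParams) -> np.ndarray:
    return bp.d_max / (1.0 + np.exp(-bp.k * (mu - bp.a0)))


def _sample_plan(config: SimulationConfig, subjects: pd.DataFrame) -> pd.DataFrame:
    """One row per hybridized sample: subject, extract, measurement, role."""
    n_subj = len(subjects)
    tech = set(range(config.n_tech_rep))
    start = config.n_tech_rep - config.n_overlap_rep
    extract = set(range(start, start + config.n_extract_rep))
    if extract and max(extract) >= n_subj:
        raise ConfigurationError("replicate sets do not fit in the subject pool")
    rows = []
    for i, subj in enumerate(subjects.itertuples(index=False)):
        order = 1
        rows.append((subj.subject_id, 1, 1, "primary", order))
        if i in tech:
            order += 1
            rows.append((subj.subject_id, 1, 2, "technical", order))
        if i in extract:
            order += 1
            rows.append((subj.subject_id, 2, 1, "extract", order))
    plan = pd.DataFrame(
        rows, columns=["subject_id", "extract", "measurement", "replicate_kind", "order_index"]
    )
    plan["sample_id"] = [
        f"{r.subject_id}.e{r.extract}m{r.measurement}" for r in plan.itertuples(index=False)
    ]
    return plan


def _panel_params(config: SimulationConfig, panel: str):
    if panel == PANEL_A:
        return config.sigma_tech_a, config.sigma_extract_a, True
    if panel == PANEL_B:
        return config.sigma_tech_b, config.sigma_extract_b, False
    raise ParameterError(f"unknown panel id {panel!r}")


def generate_panel_matrix(
    truth: TruthSet, config: SimulationConfig, panel: str
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate one panel's intensity matrix, probe manifest and metadata."""
    sigma_tech, sigma_extract, biased = _panel_params(config, panel)
    probes = truth.probes_a if panel == PANEL_A else truth.probes_b
    rng = np.random.default_rng(
        [config.seed % (2**31), 17 if panel == PANEL_A else 23]
    )

    plan = _sample_plan(config, truth.subjects)
    subj_info = truth.subjects.set_index("subject_id")
    gene_idx = {g: i for i, g in enumerate(truth.gene_ids)}
    g_of_probe = probes["gene"].map(gene_idx).to_numpy()

    mu_p = truth.mu[g_of_probe] + probes["offset"].to_numpy()
    if biased:
        mu_p = mu_p + _panel_bias(truth.mu[g_of_probe], config.bias_params)
    beta_p = truth.beta[g_of_probe]

    n_genes = len(truth.gene_ids)
    sigma_eta = float(np.sqrt(max(sigma_extract**2 - sigma_tech**2, 0.0)))
    eta: dict[tuple[str, int], np.ndarray] = {}
    cols = {}
    for s in plan.itertuples(index=False):
        info = subj_info.loc[s.subject_id]
        key = (s.subject_id, s.extract)
        if key not in eta:
            eta[key] = (
                rng.normal(0.0, sigma_eta, size=n_genes)
                if sigma_eta > 0
                else np.zeros(n_genes)
            )
        signal = (
            mu_p
            + beta_p * (info["group"] == "HER2+")
            + info["b"]
            + eta[key][g_of_probe]
            + rng.normal(0.0, sigma_tech, size=mu_p.size)
        )
        cols[s.sample_id] = np.exp2(signal)
    values = pd.DataFrame(cols, index=probes["probe_id"].to_numpy())
    values.index.name = "probe_id"
    matrix = ExpressionMatrix(panel, values, SCALE_INTENSITY)

    manifest = _build_manifest(truth, config, panel, probes)
    metadata = plan.merge(
        truth.subjects[["subject_id", "group", "her2_ihc"]], on="subject_id"
    )[METADATA_COLUMNS]
    return matrix, manifest, metadata


def _build_manifest(
    truth: TruthSet, config: SimulationConfig, panel: str, probes: pd.DataFrame
) -> pd.DataFrame:
    """Annotation table exercising all three cross-panel match tiers.

    Tier 1 genes share the symbol across panels; tier 2 genes have
    divergent symbols rescued by a shared RefSeq accession; tier 3 genes
    have divergent symbols and RefSeqs but share an Entrez id, and the
    panel-B record lists the panel-A symbol among its aliases.
    """
    gi = {g: i for i, g in enumerate(truth.gene_ids)}
    rows = []
    for p in probes.itertuples(index=False):
        g = p.gene
        i = gi[g]
        t = truth.tier[g]
        entrez = 1000 + i
        if panel == PANEL_A:
            symbol = g
            aliases = [f"{g}A1"]
            refseqs = [f"NM_{100000 + i}.1"]
        else:
            if t == 1:
                symbol, aliases, refseqs = g, [f"{g}B1"], [f"NM_{100000 + i}.2"]
            elif t == 2:
                # symbol diverges; same accession, different version suffix
                symbol, aliases, refseqs = f"{g}X", [f"{g}XB"], [f"NM_{100000 + i}.3"]
            else:
                symbol, aliases, refseqs = f"{g}Y", [g, f"{g}YB"], [f"XM_{500000 + i}.1"]
        rows.append(
            {
                "probe_id": p.probe_id,
                "panel_id": panel,
                "gene_symbol": symbol,
                "aliases": ";".join(aliases),
                "refseq_ids": ";".join(refseqs),
                "entrez_id": str(entrez),
                "sequence": p.sequence,
                "transcript_position": p.position,
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def generate_interaction_graph(truth: TruthSet, config: SimulationConfig) -> nx.DiGraph:
    """Directed curated-style graph where planted DE genes interconnect via hubs.

    Every DE gene gets a reciprocal edge pair with every hub, so any two DE
    genes are joined by a directed path of two edges through a hub.
    Distractor nodes with random edges to hubs and each other pad the graph.
    """
    if not truth.hub_genes:
        raise ConfigurationError("at least one hub gene must be designated")
    rng = np.random.default_rng([config.seed % (2**31), 29])
    graph = nx.DiGraph()
    effects = ["activation", "inhibition", "unspecified"]
    for de in truth.de_genes:
        for hub in truth.hub_genes:
            graph.add_edge(de, hub, effect=str(rng.choice(effects)), mechanism="curated")
            graph.add_edge(hub, de, effect=str(rng.choice(effects)), mechanism="curated")
    distractors = [f"DIST{i + 1:03d}" for i in range(config.n_distractors)]
    pool = distractors + truth.hub_genes
    for d in distractors:
        n_out = int(rng.integers(1, 4))
        targets = rng.choice([p for p in pool if p != d], size=n_out, replace=False)
        for t in targets:
            graph.add_edge(d, t, effect=str(rng.choice(effects)), mechanism="curated")
    return graph


def generate_dataset(config: SimulationConfig):
    """Convenience wrapper: truth, both panels, shared metadata and graph."""
    truth = generate_truth(config)
    mat_a, man_a, meta = generate_panel_matrix(truth, config, PANEL_A)
    mat_b, man_b, _ = generate_panel_matrix(truth, config, PANEL_B)
    graph = generate_interaction_graph(truth, config)
    return truth, (mat_a, man_a), (mat_b, man_b), meta, graph
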