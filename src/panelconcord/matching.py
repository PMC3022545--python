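"""Cross-panel gene correspondence and probe-level summarization.

Genes are matched across the two panels by a three-tier cascade: exact
(case-insensitive) gene-symbol equality first, then shared version-stripped
RefSeq accessions among the leftovers, then symbol/alias and Entrez-id
rescue. Separately, probe nucleotide sequences are matched exactly: a short
panel-A probe counts as matched when it occurs verbatim inside a panel-B
probe sequence. Matched probes are averaged per gene on the log2 scale to
give gene-level expression.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import AmbiguityError, ConsistencyError, ParameterError
from .io_formats import ExpressionMatrix

TIER_SYMBOL = 1
TIER_REFSEQ = 2
TIER_ALIAS_ENTREZ = 3

MATCH_COLUMNS = [
    "gene_key",
    "panelA_symbol",
    "panelB_symbol",
    "tier",
    "panelA_probe_ids",
    "panelB_probe_ids",
]


def _norm_symbol(s: str) -> str:
    return s.strip().upper()


def _strip_version(acc: str) -> str:
    acc = acc.strip().upper()
    return acc.split(".", 1)[0] if "." in acc else acc


def _split_multi(raw: str) -> list[str]:
    return [t for t in (p.strip() for p in str(raw).split(";")) if t]


def _gene_records(manifest: pd.DataFrame) -> dict[str, dict]:
    """Collapse a probe manifest to one record per (normalized) gene symbol."""
    records: dict[str, dict] = {}
    for row in manifest.itertuples(index=False):
        sym = _norm_symbol(row.gene_symbol)
        rec = records.setdefault(
            sym,
            {"symbol": row.gene_symbol, "probes": [], "aliases": set(), "refseqs": set(), "entrez": set()},
        )
        rec["probes"].append(row.probe_id)
        rec["aliases"].update(_norm_symbol(a) for a in _split_multi(row.aliases))
        rec["refseqs"].update(_strip_version(r) for r in _split_multi(row.refseq_ids))
        if row.entrez_id is not None and not pd.isna(row.entrez_id) and str(row.entrez_id) != "":
            rec["entrez"].add(int(row.entrez_id))
    return records


def _invert(records: dict[str, dict], key: str) -> dict:
    index: dict = {}
    for sym, rec in records.items():
        for v in rec[key]:
            index.setdefault(v, set()).add(sym)
    return index


def match_genes(manifest_a: pd.DataFrame, manifest_b: pd.DataFrame) -> pd.DataFrame:
    """Three-tier cross-panel gene matching; one row per matched gene.

    Raises :class:`AmbiguityError` when a gene on one panel matches more
    than one gene on the other within a tier — the mapping must be 1:1.
    """
    recs_a = _gene_records(manifest_a)
    recs_b = _gene_records(manifest_b)

    matched: dict[str, tuple[str, int]] = {}  # A symbol -> (B symbol, tier)
    used_b: dict[str, str] = {}

    def _claim(a_sym: str, candidates: set, tier: int) -> None:
        candidates = {c for c in candidates if c not in used_b}
        if not candidates:
            return
        if len(candidates) > 1:
            raise AmbiguityError(
                f"gene {recs_a[a_sym]['symbol']!r} matches multiple panel-B genes "
                f"at tier {tier}: {sorted(candidates)}"
            )
        b_sym = candidates.pop()
        matched[a_sym] = (b_sym, tier)
        used_b[b_sym] = a_sym

    # tier 1: exact symbol
    for a_sym in sorted(recs_a):
        if a_sym in recs_b:
            _claim(a_sym, {a_sym}, TIER_SYMBOL)

    # tier 2: shared version-stripped RefSeq among the unmatched
    refseq_b = _invert({s: r for s, r in recs_b.items() if s not in used_b}, "refseqs")
    for a_sym in sorted(recs_a):
        if a_sym in matched:
            continue
        cands = set()
        for acc in recs_a[a_sym]["refseqs"]:
            cands |= refseq_b.get(acc, set())
        _claim(a_sym, cands, TIER_REFSEQ)

    # tier 3: symbol-vs-alias, alias-vs-alias, or Entrez equality
    rem_b = {s: r for s, r in recs_b.items() if s not in used_b}
    alias_b = _invert(rem_b, "aliases")
    entrez_b = _invert(rem_b, "entrez")
    for a_sym in sorted(recs_a):
        if a_sym in matched:
            continue
        rec = recs_a[a_sym]
        cands = set(alias_b.get(a_sym, set()))
        for al in rec["aliases"]:
            if al in rem_b:
                cands.add(al)
            cands |= alias_b.get(al, set())
        for ez in rec["entrez"]:
            cands |= entrez_b.get(ez, set())
        _claim(a_sym, cands, TIER_ALIAS_ENTREZ)

    rows = [
        {
            "gene_key": a_sym,
            "panelA_symbol": recs_a[a_sym]["symbol"],
            "panelB_symbol": recs_b[b_sym]["symbol"],
            "tier": tier,
            "panelA_probe_ids": ";".join(recs_a[a_sym]["probes"]),
            "panelB_probe_ids": ";".join(recs_b[b_sym]["probes"]),
        }
        for a_sym, (b_sym, tier) in sorted(matched.items())
    ]
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def match_probe_sequences(manifest_a: pd.DataFrame, manifest_b: pd.DataFrame) -> pd.DataFrame:
    """All (A, B) probe pairs where A's sequence occurs verbatim inside B's.

    Exact string containment, no mismatches; the 0-based start offset of
    the first occurrence is recorded. Implemented with a substring index
    over the panel-B sequences keyed by panel-A probe length.
    """
    lengths = sorted({len(s) for s in manifest_a["sequence"]})
    index: dict[int, dict[str, list]] = {}
    for length in lengths:
        sub_index: dict[str, list] = {}
        for row in manifest_b.itertuples(index=False):
            seq = row.sequence
            for off in range(len(seq) - length + 1):
                sub_index.setdefault(seq[off : off + length], []).append((row.probe_id, off))
        index[length] = sub_index
    rows = []
    for row in manifest_a.itertuples(index=False):
        for b_probe, off in index[len(row.sequence)].get(row.sequence, []):
            rows.append(
                {"panelA_probe_id": row.probe_id, "panelB_probe_id": b_probe, "offset": off}
            )
    out = pd.DataFrame(rows, columns=["panelA_probe_id", "panelB_probe_id", "offset"])
    return out.sort_values(["panelA_probe_id", "panelB_probe_id"]).reset_index(drop=True)


def summarize_gene_level(
    matrix: ExpressionMatrix, matches: pd.DataFrame, panel_side: str
) -> ExpressionMatrix:
    """Average log2 probe values per matched gene; rows ordered by gene_key.

    ``panel_side`` selects which panel's probe lists to use ('A' or 'B').
    """
    if panel_side not in ("A", "B"):
        raise ParameterError(f"panel_side must be 'A' or 'B', got {panel_side!r}")
    if matrix.scale != "log2":
        raise ParameterError("gene-level summarization expects log2 values")
    col = f"panel{panel_side}_probe_ids"
    ordered = matches.sort_values("gene_key")
    rows = {}
    for row in ordered.itertuples(index=False):
        probe_ids = getattr(row, col).split(";")
        missing = [p for p in probe_ids if p not in matrix.values.index]
        if missing:
            raise ConsistencyError(
                f"gene {row.gene_key!r}: probes {missing} absent from matrix"
            )
        rows[row.gene_key] = matrix.values.loc[probe_ids].mean(axis=0)
    gene_values = pd.DataFrame(rows).T
    gene_values.index.name = "gene_key"
    gene_values.columns = matrix.values.columns
    return ExpressionMatrix(matrix.panel_id, gene_values, "log2")
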