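"""File formats, run configuration and report writing.

Formats
-------
* Network: tab-separated edge list, one ``parent<TAB>child`` per line,
  ``#`` comments allowed.
* Roles: tab-separated ``node<TAB>role1,role2,...`` with roles from
  {ligand, receptor, observed, inhibitable, hidden}.
* Similarity: long-form TSV with header ``gene_a  gene_b  score`` (preferred)
  or a square matrix TSV with node names as header row/column.
* Measurements: MIDAS-like CSV -- ``TR:<ligand>`` 0/1 stimulus columns,
  ``TR:<node>i`` 0/1 inhibitor columns, a ``DA:`` time column (minutes) and
  ``DV:<protein>`` value columns; an optional ``ID:condition`` column names
  conditions.  A plain long-form TSV (condition, time, protein, value) plus
  a design TSV is also accepted.
* Fitted model: YAML mapping node -> {beta0, betas, mu0, mu1, sigma0, sigma1}.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .mcem import ExperimentTable, MCEMConfig, NodeParameters, Record
from .network import (
    NetworkError,
    SignalingNetwork,
    collapse_to_observed,
    load_network,
)

__all__ = [
    "FormatError",
    "RunConfig",
    "read_network_file",
    "read_roles_file",
    "read_network",
    "write_network",
    "write_roles",
    "read_similarity",
    "write_similarity",
    "read_midas",
    "write_midas",
    "read_long_form",
    "params_to_yaml",
    "params_from_yaml",
    "write_report",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """All pipeline tunables; echoed into every output directory."""

    seed: int = 0
    n_candidates: int = 50
    n_moves: int = 10
    max_rejections: int = 1000
    n_prediction_samples: int = 50
    prediction_burn_in: int = 200
    mcem: MCEMConfig = dataclasses.field(default_factory=MCEMConfig)

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        mcem_kwargs = payload.pop("mcem", {})
        if "lasso_grid" in mcem_kwargs:
            mcem_kwargs["lasso_grid"] = tuple(mcem_kwargs["lasso_grid"])
        mcem = MCEMConfig(**mcem_kwargs)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**payload, mcem=mcem)
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


# ---------------------------------------------------------------------------
# network / roles / similarity
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> list[str]:
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def read_network_file(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    for line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"expected 'parent<TAB>child', got {line!r}")
        edges.append((parts[0].strip(), parts[1].strip()))
    return edges


def read_roles_file(path: str | Path) -> dict[str, tuple[str, ...]]:
    roles: dict[str, tuple[str, ...]] = {}
    for line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"expected 'node<TAB>role1,role2,...', got {line!r}")
        roles[parts[0].strip()] = tuple(
            r.strip() for r in parts[1].split(",") if r.strip()
        )
    return roles


def read_network(
    network_path: str | Path, roles_path: str | Path, name: str | None = None
) -> SignalingNetwork:
    return load_network(
        read_network_file(network_path),
        read_roles_file(roles_path),
        name=name or Path(network_path).stem,
    )


def write_network(net: SignalingNetwork, path: str | Path) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(net.edges)]
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


def write_roles(net: SignalingNetwork, path: str | Path) -> None:
    lines = [
        f"{n}\t{','.join(net.role(n).names())}" for n in sorted(net.nodes)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_similarity(path: str | Path) -> dict[tuple[str, str], float]:
    """Read pairwise similarity scores (long form or square matrix)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and "score" in cols:
        scores: dict[tuple[str, str], float] = {}
        a_col, b_col = df.columns[0], df.columns[1]
        s_col = df.columns[cols.index("score")]
        for _, row in df.iterrows():
            a, b = str(row[a_col]), str(row[b_col])
            if a == b:
                continue
            scores[tuple(sorted((a, b)))] = float(row[s_col])
        return scores
    # square matrix: first column holds row names
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if list(mat.index) != list(mat.columns):
        raise FormatError(
            "similarity matrix must have identical row and column names"
        )
    scores = {}
    names = [str(n) for n in mat.index]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            scores[tuple(sorted((a, b)))] = float(mat.loc[a, b])
    return scores


def write_similarity(
    scores: Mapping[tuple[str, str], float], path: str | Path
) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "score": s}
        for (a, b), s in sorted(scores.items())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def read_midas(path: str | Path) -> ExperimentTable:
    """Parse a MIDAS-like CSV into an experiment table.

    ``TR:`` columns are 0/1 treatments (an ``i`` suffix marks an inhibitor of
    the stripped node name), ``DA:`` is the time in minutes, ``DV:`` columns
    hold readings (blank = missing).  Raises on unknown column prefixes and
    on duplicate (condition, time) rows.
    """
    df = pd.read_csv(path)
    stim_cols: dict[str, str] = {}
    inhib_cols: dict[str, str] = {}
    dv_cols: dict[str, str] = {}
    da_col = None
    id_col = None
    for col in df.columns:
        if col.startswith("ID:"):
            id_col = col
        elif col.startswith("TR:"):
            name = col[3:]
            if name.endswith("i"):
                inhib_cols[col] = name[:-1]
            else:
                stim_cols[col] = name
        elif col.startswith("DA:"):
            da_col = col
        elif col.startswith("DV:"):
            dv_cols[col] = col[3:]
        else:
            raise FormatError(
                f"unknown column prefix in header {col!r} "
                "(expected ID:, TR:, DA: or DV:)"
            )
    records = []
    seen: set[tuple[str, float]] = set()
    for ridx, row in df.iterrows():
        condition = str(row[id_col]) if id_col else f"r{ridx:03d}"
        time = float(row[da_col]) if da_col else 0.0
        key = (condition, time)
        if key in seen:
            raise FormatError(
                f"duplicate (condition, time) = {key!r}: conflicting readings"
            )
        seen.add(key)
        stimuli = frozenset(
            n for c, n in stim_cols.items() if float(row[c]) == 1.0
        )
        inhibited = frozenset(
            n for c, n in inhib_cols.items() if float(row[c]) == 1.0
        )
        readings = {}
        for c, prot in dv_cols.items():
            v = row[c]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            readings[prot] = float(v)
        records.append(
            Record(condition=condition, time=time, stimuli=stimuli,
                   inhibited=inhibited, readings=readings)
        )
    return ExperimentTable(records)


def write_midas(table: ExperimentTable, path: str | Path) -> None:
    stimuli = sorted({s for rec in table.records for s in rec.stimuli})
    inhibited = sorted({i for rec in table.records for i in rec.inhibited})
    proteins = sorted({p for rec in table.records for p in rec.readings})
    rows = []
    for rec in table.records:
        row: dict[str, object] = {"ID:condition": rec.condition}
        for s in stimuli:
            row[f"TR:{s}"] = int(s in rec.stimuli)
        for i in inhibited:
            row[f"TR:{i}i"] = int(i in rec.inhibited)
        row["DA:time"] = rec.time
        for p in proteins:
            row[f"DV:{p}"] = rec.readings.get(p, np.nan)
        rows.append(row)
    cols = (
        ["ID:condition"]
        + [f"TR:{s}" for s in stimuli]
        + [f"TR:{i}i" for i in inhibited]
        + ["DA:time"]
        + [f"DV:{p}" for p in proteins]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_long_form(
    readings_path: str | Path, design_path: str | Path
) -> ExperimentTable:
    """Long-form TSV (condition, time, protein, value) + design TSV
    (condition, stimuli, inhibited; comma-separated sets, blank allowed)."""
    readings = pd.read_csv(readings_path, sep="\t")
    design = pd.read_csv(design_path, sep="\t").fillna("")
    need = {"condition", "time", "protein", "value"}
    if not need.issubset(readings.columns):
        raise FormatError(f"long-form readings need columns {sorted(need)}")
    if "condition" not in design.columns:
        raise FormatError("design file needs a 'condition' column")

    def parse_set(text: object) -> frozenset:
        return frozenset(
            t.strip() for t in str(text).split(",") if t.strip()
        )

    clamps = {
        str(row["condition"]): (
            parse_set(row.get("stimuli", "")),
            parse_set(row.get("inhibited", "")),
        )
        for _, row in design.iterrows()
    }
    records = {}
    for _, row in readings.iterrows():
        cond = str(row["condition"])
        if cond not in clamps:
            raise FormatError(f"condition {cond!r} missing from design file")
        key = (cond, float(row["time"]))
        rec = records.setdefault(key, {})
        prot = str(row["protein"])
        if prot in rec:
            raise FormatError(
                f"duplicate reading for {(cond, row['time'], prot)!r}"
            )
        rec[prot] = float(row["value"])
    return ExperimentTable(
        [
            Record(
                condition=cond, time=time, stimuli=clamps[cond][0],
                inhibited=clamps[cond][1], readings=vals,
            )
            for (cond, time), vals in sorted(records.items())
        ]
    )


# ---------------------------------------------------------------------------
# fitted model + report
# ---------------------------------------------------------------------------


def params_to_yaml(params: Mapping[str, NodeParameters]) -> str:
    payload = {}
    for node, pr in params.items():
        entry: dict[str, object] = {
            "beta0": float(pr.beta0),
            "betas": {p: float(b) for p, b in pr.betas.items()},
        }
        if pr.has_emissions:
            entry.update(
                mu0=float(pr.mu0), mu1=float(pr.mu1),
                sigma0=float(pr.sigma0), sigma1=float(pr.sigma1),
            )
        payload[node] = entry
    return yaml.safe_dump(payload, sort_keys=True)


def params_from_yaml(text: str) -> dict[str, NodeParameters]:
    payload = yaml.safe_load(text) or {}
    out = {}
    for node, entry in payload.items():
        out[str(node)] = NodeParameters(
            beta0=float(entry["beta0"]),
            betas={str(p): float(b) for p, b in (entry.get("betas") or {}).items()},
            mu0=entry.get("mu0"),
            mu1=entry.get("mu1"),
            sigma0=entry.get("sigma0"),
            sigma1=entry.get("sigma1"),
        )
    return out


def write_report(selected, out_dir: str | Path, collapsed=None) -> dict[str, Path]:
    """Write the artifact files for a selected (fitted) candidate.

    Emits the full network, the hidden-node-collapsed network, the fitted
    parameters, the candidate BIC table when available, and a text summary.
    Raises if the structure has no observed node (nothing to collapse onto).
    """
    from .search import ScoredCandidate, SearchResult

    if isinstance(selected, SearchResult):
        pool = selected.candidates
        best: ScoredCandidate = selected.best
        table = selected.table()
    else:
        best = selected
        pool = [selected]
        table = None
    net = best.network
    if not net.observed_nodes:
        raise NetworkError("selected network has no observed nodes to report")
    if collapsed is None:
        collapsed = collapse_to_observed(net)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "selected_network.tsv",
        "roles": out / "selected_roles.tsv",
        "collapsed": out / "collapsed_network.tsv",
        "params": out / "parameters.yaml",
        "bic": out / "bic_table.tsv",
        "summary": out / "summary.txt",
    }
    write_network(net, paths["network"])
    write_roles(net, paths["roles"])
    write_network(collapsed, paths["collapsed"])
    paths["params"].write_text(params_to_yaml(best.params))
    if table is None:
        table = [
            {
                "candidate": 0,
                "seed": getattr(best, "seed", 0),
                "loglik": best.loglik,
                "k": getattr(best, "k", float("nan")),
                "bic": getattr(best, "bic", float("nan")),
                "n_edges": net.n_edges,
                "converged": getattr(best, "converged", True),
            }
        ]
    pd.DataFrame(table).to_csv(paths["bic"], sep="\t", index=False)
    pruned = getattr(best, "pruned_edges", ())
    summary = [
        f"selected network: {net.n_nodes} nodes, {net.n_edges} edges",
        f"collapsed network: {collapsed.n_nodes} nodes, "
        f"{collapsed.n_edges} edges",
        f"log-likelihood: {best.loglik:.4f}",
        f"BIC: {getattr(best, 'bic', float('nan')):.4f}",
        f"candidates fitted: {len(pool)}",
        f"edges pruned by L1 in the final round: {len(pruned)}"
        + (f" ({', '.join('->'.join(e) for e in pruned)})" if pruned else ""),
    ]
    paths["summary"].write_text("\n".join(summary) + "\n")
    return paths
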