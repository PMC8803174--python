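"""Serialization of networks, archives, weight tables and entropy estimates.

All formats are plain text.  A network file is a tab-separated edge list with
``# key=value`` header comments carrying the model parameters:

    # N=32
    # K=80
    # beta=2.0
    # mu=0.0
    # input=0
    # output=31
    source	target	sign
    0	5	1
    ...

Sample archives are newline-delimited records (optionally gzipped), one per
line: ``mcs<TAB>fitness<TAB>edge;edge;...`` with each edge ``src:dst:sign``.
Weight tables and entropy estimates are CSV with header rows.  All floats are
written with full double precision (repr round-trip).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

from grnevo.model import ModelParams, RegulatoryNetwork
from grnevo.mucamc import (
    EntropyEstimate,
    FitnessBinning,
    SampleArchive,
    SampleRecord,
    WeightTable,
)

__all__ = [
    "read_network",
    "write_network",
    "read_archive",
    "write_archive",
    "read_weight_table",
    "write_weight_table",
    "write_entropy",
    "read_entropy",
]

PathLike = Union[str, Path]


class NetworkFormatError(ValueError):
    """Raised for malformed or invariant-violating network files."""


def write_network(net: RegulatoryNetwork, path: PathLike) -> None:
    p = net.params
    lines = [
        f"# N={p.n_nodes}",
        f"# K={p.n_edges}",
        f"# beta={p.beta!r}",
        f"# mu={p.mu!r}",
        f"# input={p.input_index}",
        f"# output={p.output_index}",
        "source\ttarget\tsign",
    ]
    for s, d, g in zip(net.src.tolist(), net.dst.tolist(), net.sign.tolist()):
        lines.append(f"{s}\t{d}\t{g:+d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: PathLike) -> RegulatoryNetwork:
    """Read an edge-list file; raises :class:`NetworkFormatError` with the
    offending line number for malformed input."""
    meta: dict[str, str] = {}
    src, dst, sgn = [], [], []
    seen: set[tuple[int, int]] = set()
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            if line.split("\t") != ["source", "target", "sign"]:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected header 'source\\ttarget\\tsign'"
                )
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 3 tab-separated fields"
            )
        try:
            s, d, g = (int(x) for x in parts)
        except ValueError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: {exc}") from None
        if g not in (-1, 1):
            raise NetworkFormatError(
                f"{path}:{lineno}: sign must be -1 or +1, got {g}"
            )
        if (s, d) in seen:
            raise NetworkFormatError(
                f"{path}:{lineno}: duplicate ordered pair ({s}, {d})"
            )
        seen.add((s, d))
        src.append(s)
        dst.append(d)
        sgn.append(g)
    try:
        params = ModelParams(
            n_nodes=int(meta["N"]),
            n_edges=int(meta["K"]),
            beta=float(meta.get("beta", 2.0)),
            mu=float(meta.get("mu", 0.0)),
            output_index=int(meta.get("output", -1)),
        )
    except KeyError as exc:
        raise NetworkFormatError(f"{path}: missing header comment {exc}") from None
    if len(src) != params.n_edges:
        raise NetworkFormatError(
            f"{path}: {len(src)} edges but header says K={params.n_edges}"
        )
    try:
        return RegulatoryNetwork(
            params, np.array(src), np.array(dst), np.array(sgn)
        )
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from None


def _serialize_edges(net: RegulatoryNetwork) -> str:
    return ";".join(
        f"{s}:{d}:{g:+d}"
        for s, d, g in zip(
            net.src.tolist(), net.dst.tolist(), net.sign.tolist()
        )
    )


def _parse_edges(
    text: str, params: ModelParams
) -> RegulatoryNetwork:
    src, dst, sgn = [], [], []
    for item in text.split(";"):
        s, d, g = item.split(":")
        src.append(int(s))
        dst.append(int(d))
        sgn.append(int(g))
    return RegulatoryNetwork(params, np.array(src), np.array(dst), np.array(sgn))


def _open_text(path: PathLike, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_archive(archive: SampleArchive, path: PathLike) -> None:
    meta = archive.metadata
    params: ModelParams = meta["params"]
    with _open_text(path, "w") as fh:
        fh.write(f"# N={params.n_nodes}\n# K={params.n_edges}\n")
        fh.write(f"# beta={params.beta!r}\n# mu={params.mu!r}\n")
        fh.write(f"# output={params.output_index}\n")
        if meta.get("seed") is not None:
            fh.write(f"# seed={meta['seed']}\n")
        for r in archive.records:
            fh.write(f"{r.mcs}\t{r.fitness!r}\t{_serialize_edges(r.network)}\n")


def read_archive(path: PathLike) -> SampleArchive:
    meta: dict[str, str] = {}
    records: list[SampleRecord] = []
    params: ModelParams | None = None
    with _open_text(path, "r") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if params is None:
                params = ModelParams(
                    n_nodes=int(meta["N"]),
                    n_edges=int(meta["K"]),
                    beta=float(meta.get("beta", 2.0)),
                    mu=float(meta.get("mu", 0.0)),
                    output_index=int(meta.get("output", -1)),
                )
            mcs, fit, edges = line.split("\t")
            records.append(
                SampleRecord(int(mcs), float(fit), _parse_edges(edges, params))
            )
    out = SampleArchive(records=records, metadata={"params": params})
    if "seed" in meta:
        out.metadata["seed"] = int(meta["seed"])
    return out


def write_weight_table(table: WeightTable, path: PathLike) -> None:
    edges = table.binning.edges
    df = pd.DataFrame(
        {
            "bin_index": np.arange(table.binning.n_bins),
            "f_lo": edges[:-1],
            "f_hi": edges[1:],
            "log_weight": table.log_weights,
            "visits": table.visit_histogram,
            "visited": table.visited.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# converged={table.converged}"
            f" final_ln_factor={table.final_ln_factor!r}"
            f" mcs_used={table.mcs_used}\n"
        )
        df.to_csv(fh, index=False, float_format="%.17g")


def read_weight_table(path: PathLike) -> WeightTable:
    meta_line = Path(path).read_text().splitlines()[0]
    df = pd.read_csv(path, comment="#")
    meta = dict(
        kv.split("=") for kv in meta_line.lstrip("#").strip().split()
    )
    return WeightTable(
        binning=FitnessBinning(n_bins=len(df)),
        log_weights=df["log_weight"].to_numpy(),
        visit_histogram=df["visits"].to_numpy(),
        visited=df["visited"].to_numpy().astype(bool),
        converged=meta.get("converged", "True") == "True",
        final_ln_factor=float(meta.get("final_ln_factor", 0.0)),
        mcs_used=int(meta.get("mcs_used", 0)),
    )


def write_entropy(est: EntropyEstimate, path: PathLike) -> None:
    edges = est.binning.edges
    pd.DataFrame(
        {
            "bin_index": np.arange(est.binning.n_bins),
            "f_lo": edges[:-1],
            "f_hi": edges[1:],
            "omega": est.omega,
            "log10_omega": est.log10_omega,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_entropy(path: PathLike) -> EntropyEstimate:
    df = pd.read_csv(path)
    return EntropyEstimate(
        binning=FitnessBinning(n_bins=len(df)),
        omega=df["omega"].to_numpy(),
        log10_omega=df["log10_omega"].to_numpy(),
    )
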