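"""Reading signals, writing segment tables, and the batch pipeline.

The input convention is a plain-text file with one numeric value per line
(blank lines and ``#`` comments are skipped).  A two-column whitespace- or
tab-separated variant ``chromosome<TAB>value`` is also accepted and splits
into one signal per chromosome label, in order of first appearance.

Outputs are a TSV segment table (0-based half-open coordinates by default,
``one_based=True`` for 1-based inclusive paper-style reporting) and a JSON
audit report of the pruning pass.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import segment_signal
from .prune import SegmentationResult
from .signals import CopyNumberSignal

__all__ = [
    "read_signal",
    "read_signals",
    "write_segments",
    "read_segments",
    "write_bed",
    "write_prune_report",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("dbseg")


def read_signals(path) -> list[CopyNumberSignal]:
    """Parse a signal file into one signal per chromosome label.

    Single-column files yield one unlabeled signal; two-column files are
    grouped by their first field.  Non-numeric or non-finite values raise
    an error naming the offending line.
    """
    path = Path(path)
    groups: dict[str | None, list[float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            label, token = (None, parts[0]) if len(parts) == 1 else (parts[0], parts[1])
            try:
                value = float(token)
            except ValueError:
                raise ValueError(
                    f"{path.name}, line {lineno}: {token!r} is not numeric"
                ) from None
            if not np.isfinite(value):
                raise ValueError(f"{path.name}, line {lineno}: non-finite value")
            groups.setdefault(label, []).append(value)
    if not groups:
        raise ValueError(f"{path.name}: no data lines")
    signals = [CopyNumberSignal(v, label=k) for k, v in groups.items()]
    for sig in signals:
        log.info(
            "read %s: n=%d mean=%.4f sd=%.4f",
            sig.label or path.name,
            sig.n,
            sig.values.mean(),
            sig.values.std(ddof=1) if sig.n > 1 else 0.0,
        )
    return signals


def read_signal(path) -> CopyNumberSignal:
    """Read a file expected to hold a single signal."""
    signals = read_signals(path)
    if len(signals) > 1:
        raise ValueError(
            f"{Path(path).name} holds {len(signals)} chromosomes; use read_signals()"
        )
    return signals[0]


def _segments_frame(result: SegmentationResult, one_based: bool) -> pd.DataFrame:
    edges = result.edges
    start = edges[:-1] + (1 if one_based else 0)
    end = edges[1:]  # exclusive if 0-based, inclusive last probe if 1-based
    sig = [""] + [repr(float(z)) for z in result.significances]
    return pd.DataFrame(
        {
            "segment_index": np.arange(result.n_segments),
            "start": start,
            "end": end,
            "n_probes": np.diff(edges),
            "mean": result.means,
            "breakpoint_significance": sig,
        }
    )


def write_segments(result: SegmentationResult, path, one_based: bool = False) -> None:
    """Write the final segment table as TSV.

    Columns: segment_index, start, end, n_probes, mean,
    breakpoint_significance (Z of the breakpoint at ``start``; empty for
    the first segment).  Floats use repr precision so a round trip
    preserves them bit-exactly.
    """
    frame = _segments_frame(result, one_based)
    frame["mean"] = [repr(float(m)) for m in frame["mean"]]
    frame.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    """Read a segment TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"breakpoint_significance": str})


def write_bed(result: SegmentationResult, path, chrom: str | None = None) -> None:
    """BED-style export: chrom, start, end, mean (0-based half-open)."""
    edges = result.edges
    frame = pd.DataFrame(
        {
            "chrom": chrom or result.label or "chr?",
            "start": edges[:-1],
            "end": edges[1:],
            "mean": [repr(float(m)) for m in result.means],
        }
    )
    frame.to_csv(path, sep="\t", index=False, header=False)


def write_prune_report(result: SegmentationResult, path) -> None:
    """Serialize the pruning audit (sigma-hat, eta, sigma', kept/removed)."""
    payload = {"sigma_hat": result.sigma_hat, "n_probes": result.n}
    if result.report is not None:
        payload.update(result.report.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_signal(values, path) -> None:
    """Write a signal as one value per line (the segmenter's input format)."""
    arr = np.asarray(values, dtype=np.float64).reshape(-1)
    with open(path, "w") as fh:
        for v in arr:
            fh.write(f"{float(v)!r}\n")


def write_truth(profile, path) -> None:
    """Ground-truth TSV of a simulated profile: start, end, copy_number,
    true_mean (0-based half-open)."""
    edges = profile.true_edges
    frame = pd.DataFrame(
        {
            "start": edges[:-1],
            "end": edges[1:],
            "copy_number": profile.levels,
            "true_mean": [repr(float(m)) for m in profile.true_means],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class TruthTable:
    """Ground truth read back from a TSV; quacks like a SimulatedProfile
    for gold-standard sampling and segment counting."""

    n: int
    true_breakpoints: np.ndarray
    true_means: np.ndarray
    levels: np.ndarray

    @property
    def true_edges(self) -> np.ndarray:
        return np.concatenate(([0], self.true_breakpoints, [self.n]))


def read_truth(path) -> TruthTable:
    frame = pd.read_csv(path, sep="\t")
    return TruthTable(
        n=int(frame["end"].iloc[-1]),
        true_breakpoints=frame["start"].to_numpy(dtype=np.int64)[1:],
        true_means=frame["true_mean"].to_numpy(dtype=np.float64),
        levels=frame["copy_number"].to_numpy(dtype=np.int64),
    )


@dataclass
class RunConfig:
    """Flat, text-serializable configuration of one pipeline run."""

    input: str
    output_dir: str = "dbs_out"
    theta: float = 0.05
    gamma: float = 0.02
    lam: float = 0.02
    min_seg_len: int = 20
    window_ratio: int = 2
    k_loc: float = 4.0
    winsorize: bool = True
    winsor_tau: float = 2.5
    median_window: int = 0  # 0 disables the median filter
    iterate_prune: bool = False
    one_based: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # fail fast, before any computation
        from .preprocess import WinsorizeParams
        from .segment import DBSParams

        DBSParams(
            theta=self.theta,
            gamma=self.gamma,
            lam=self.lam,
            n0=self.min_seg_len,
            window_ratio=self.window_ratio,
            k_loc=self.k_loc,
        )
        if self.winsorize:
            WinsorizeParams(self.winsor_tau)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.type == "bool":
                kwargs[f.name] = v in ("True", "true", "1")
            elif f.type == "int":
                kwargs[f.name] = int(v)
            elif f.type == "float":
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


def run_pipeline(config: RunConfig) -> list[SegmentationResult]:
    """Preprocess, estimate noise, segment, prune, and write all artifacts.

    Writes ``<stem>.segments.tsv`` and ``<stem>.prune.json`` per input
    chromosome into ``config.output_dir``, plus the resolved config.
    Deterministic given the config.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    signals = read_signals(config.input)
    stem = Path(config.input).stem
    results = []
    for sig in signals:
        result = segment_signal(
            sig,
            theta=config.theta,
            gamma=config.gamma,
            lam=config.lam,
            min_seg_len=config.min_seg_len,
            window_ratio=config.window_ratio,
            k_loc=config.k_loc,
            winsorize=config.winsorize,
            winsor_tau=config.winsor_tau,
            median_window=config.median_window or None,
            iterate_prune=config.iterate_prune,
        )
        rep = result.report
        log.info(
            "%s: sigma_hat=%.4f candidates=%d eta=%s sigma_prime=%.4f kept=%d segments=%d",
            sig.label or stem,
            result.sigma_hat,
            len(rep.kept) + len(rep.removed),
            f"{rep.eta:.4f}" if np.isfinite(rep.eta) else "inf",
            rep.sigma_prime,
            len(rep.kept),
            result.n_segments,
        )
        tag = f".{sig.label}" if sig.label else ""
        write_segments(result, out / f"{stem}{tag}.segments.tsv", config.one_based)
        write_prune_report(result, out / f"{stem}{tag}.prune.json")
        results.append(result)
    config.to_file(out / "run_config.txt")
    return results
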