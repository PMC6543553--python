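"""Delimited-text file formats and deterministic seed derivation.

All artifacts are plain text with versioned ``#``-prefixed headers: STRFs
and dynamic spectra as whitespace-delimited matrices, spike/discharge trains
as two-column (index, time) files, genomes as explicit integer matrices,
sensitivity profiles as label/score pairs, and comparison diagrams as edge
lists.  Readers validate strictly and report the offending line number.

Seed derivation: every stochastic stage derives its seed from the master
seed via ``split_seed(master, label)`` — a SeedSequence keyed on the master
seed plus the CRC-32 of the stage label — so reruns with the same master
seed are bit-identical while stages stay statistically independent.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np

from .network import Genome
from .periphery import DischargeTrain
from .sensitivity import SensitivityProfile, StateComparison
from .strf import STRF
from .torc import DynamicSpectrum

__all__ = [
    "ParseError",
    "split_seed",
    "write_strf",
    "read_strf",
    "write_spikes",
    "read_spikes",
    "write_train",
    "read_train",
    "write_genome",
    "read_genome",
    "write_profile",
    "read_profile",
    "write_dynamic_spectrum",
    "read_dynamic_spectrum",
    "write_diagram",
    "write_history",
]


class ParseError(ValueError):
    """Malformed artifact file; message carries the file and line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def split_seed(master: int, label: str) -> int:
    """Deterministic sub-seed (< 2**31) for a named pipeline stage."""
    crc = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master), crc])
    return int(ss.generate_state(1)[0] % 2**31)


def _read_lines(path) -> list[str]:
    return Path(path).read_text().splitlines()


def _header_value(lines, path, key: str) -> tuple[str, int]:
    for i, ln in enumerate(lines):
        if ln.startswith(f"# {key} "):
            return ln[len(f"# {key} ") :].strip(), i
    raise ParseError(path, 0, f"missing header '# {key} ...'")


# ---------------------------------------------------------------- STRF


def write_strf(path, strf: STRF) -> None:
    with open(path, "w") as fh:
        fh.write("# strfnet strf v1\n")
        fh.write(f"# lag_step_ms {float(strf.lag_step_ms)!r}\n")
        fh.write("# freqs_hz " + " ".join(repr(float(f)) for f in strf.freqs_hz) + "\n")
        np.savetxt(fh, strf.values, fmt="%.10e")


def read_strf(path) -> STRF:
    lines = _read_lines(path)
    if not lines or not lines[0].startswith("# strfnet strf"):
        raise ParseError(path, 1, "not a strfnet STRF file")
    lag_step, _ = _header_value(lines, path, "lag_step_ms")
    freqs, _ = _header_value(lines, path, "freqs_hz")
    freqs_hz = np.array([float(x) for x in freqs.split()])
    rows = []
    for i, ln in enumerate(lines):
        if ln.startswith("#") or not ln.strip():
            continue
        try:
            row = [float(x) for x in ln.split()]
        except ValueError as exc:
            raise ParseError(path, i + 1, f"bad matrix row: {exc}") from None
        if len(row) != len(freqs_hz):
            raise ParseError(
                path, i + 1, f"expected {len(freqs_hz)} columns, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise ParseError(path, len(lines), "no matrix rows")
    return STRF(np.array(rows), float(lag_step), freqs_hz)


# ---------------------------------------------------------------- spikes / trains


def _write_indexed_times(path, header: str, unit: str, seqs, duration) -> None:
    with open(path, "w") as fh:
        fh.write(f"# strfnet {header} v1\n")
        fh.write(f"# duration_{unit} {float(duration)!r}\n")
        fh.write(f"# columns index time_{unit}\n")
        for idx, times in enumerate(seqs):
            for t in times:
                fh.write(f"{idx}\t{float(t)!r}\n")


def _read_indexed_times(path, header: str, unit: str):
    lines = _read_lines(path)
    if not lines or not lines[0].startswith(f"# strfnet {header}"):
        raise ParseError(path, 1, f"not a strfnet {header} file")
    duration, _ = _header_value(lines, path, f"duration_{unit}")
    events: dict[int, list[float]] = {}
    max_idx = -1
    for i, ln in enumerate(lines):
        if ln.startswith("#") or not ln.strip():
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise ParseError(path, i + 1, "expected two columns: index, time")
        try:
            idx, t = int(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(path, i + 1, str(exc)) from None
        if idx < 0:
            raise ParseError(path, i + 1, "negative index")
        bucket = events.setdefault(idx, [])
        if bucket and t <= bucket[-1]:
            raise ParseError(path, i + 1, f"times for index {idx} not strictly increasing")
        bucket.append(t)
        max_idx = max(max_idx, idx)
    seqs = tuple(np.array(events.get(i, []), dtype=float) for i in range(max_idx + 1))
    return seqs, float(duration)


def write_spikes(path, record) -> None:
    """Cortical spike record: two columns (neuron index, spike time ms)."""
    _write_indexed_times(path, "spikes", "ms", record.spike_times_ms, record.duration_ms)


def read_spikes(path):
    from .network import SpikeRecord

    seqs, duration = _read_indexed_times(path, "spikes", "ms")
    return SpikeRecord(seqs, duration)


def write_train(path, train: DischargeTrain) -> None:
    """Peripheral discharge train: two columns (channel index, event time s)."""
    _write_indexed_times(path, "train", "s", train.times_s, train.duration_s)


def read_train(path) -> DischargeTrain:
    seqs, duration = _read_indexed_times(path, "train", "s")
    return DischargeTrain(seqs, duration)


# ---------------------------------------------------------------- genome


def write_genome(path, genome: Genome) -> None:
    n = genome.n_neurons
    with open(path, "w") as fh:
        fh.write("# strfnet genome v1\n")
        fh.write(f"# n_neurons {n}\n")
        fh.write("# w rows: presynaptic neuron; columns: postsynaptic neuron\n")
        for row in genome.w:
            fh.write(" ".join(str(int(x)) for x in row) + "\n")
        fh.write("istr " + " ".join(str(int(x)) for x in genome.istr) + "\n")
        fh.write("idel " + " ".join(str(int(x)) for x in genome.idel) + "\n")


def read_genome(path) -> Genome:
    from .network import GENE_HIGH, GENE_LOW

    lines = _read_lines(path)
    if not lines or not lines[0].startswith("# strfnet genome"):
        raise ParseError(path, 1, "not a strfnet genome file")
    n_str, _ = _header_value(lines, path, "n_neurons")
    n = int(n_str)
    w_rows: list[list[int]] = []
    istr = idel = None
    for i, ln in enumerate(lines):
        if ln.startswith("#") or not ln.strip():
            continue
        parts = ln.split()
        if parts[0] in ("istr", "idel"):
            vals = parts[1:]
        else:
            vals = parts
        try:
            nums = [int(x) for x in vals]
        except ValueError as exc:
            raise ParseError(path, i + 1, str(exc)) from None
        if len(nums) != n:
            raise ParseError(path, i + 1, f"expected {n} entries, got {len(nums)}")
        for col, v in enumerate(nums):
            if v < GENE_LOW or v > GENE_HIGH:
                raise ParseError(
                    path,
                    i + 1,
                    f"entry {v} out of range [{GENE_LOW}, {GENE_HIGH}] at column {col + 1}",
                )
        if parts[0] == "istr":
            istr = nums
        elif parts[0] == "idel":
            idel = nums
        else:
            w_rows.append(nums)
    if len(w_rows) != n or istr is None or idel is None:
        raise ParseError(path, len(lines), "incomplete genome (w rows, istr, idel)")
    return Genome(np.array(w_rows), np.array(istr), np.array(idel))


# ---------------------------------------------------------------- profiles


def write_profile(path, profile: SensitivityProfile) -> None:
    with open(path, "w") as fh:
        fh.write("# strfnet profile v1\n")
        fh.write(f"# n_neurons {profile.n_neurons}\n")
        for label, score in zip(profile.labels, profile.scores):
            fh.write(f"{label}\t{float(score)!r}\n")


def read_profile(path) -> SensitivityProfile:
    lines = _read_lines(path)
    if not lines or not lines[0].startswith("# strfnet profile"):
        raise ParseError(path, 1, "not a strfnet profile file")
    n_str, _ = _header_value(lines, path, "n_neurons")
    n = int(n_str)
    scores = []
    for i, ln in enumerate(lines):
        if ln.startswith("#") or not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ParseError(path, i + 1, "expected label<TAB>score")
        scores.append(float(parts[1]))
    if len(scores) != n * n + 2 * n:
        raise ParseError(path, len(lines), f"expected {n * n + 2 * n} scores")
    return SensitivityProfile(np.array(scores), n)


# ---------------------------------------------------------------- dynamic spectra


def write_dynamic_spectrum(path, dspec: DynamicSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write("# strfnet dspec v1\n")
        fh.write(f"# time_step_s {float(dspec.time_step_s)!r}\n")
        fh.write("# freqs_hz " + " ".join(repr(float(f)) for f in dspec.freqs_hz) + "\n")
        np.savetxt(fh, dspec.values, fmt="%.10e")


def read_dynamic_spectrum(path) -> DynamicSpectrum:
    lines = _read_lines(path)
    if not lines or not lines[0].startswith("# strfnet dspec"):
        raise ParseError(path, 1, "not a strfnet dynamic-spectrum file")
    step, _ = _header_value(lines, path, "time_step_s")
    freqs, _ = _header_value(lines, path, "freqs_hz")
    freqs_hz = np.array([float(x) for x in freqs.split()])
    rows = []
    for i, ln in enumerate(lines):
        if ln.startswith("#") or not ln.strip():
            continue
        row = [float(x) for x in ln.split()]
        if len(row) != len(freqs_hz):
            raise ParseError(path, i + 1, f"expected {len(freqs_hz)} columns")
        rows.append(row)
    octaves = np.log2(freqs_hz / freqs_hz[0])
    return DynamicSpectrum(np.array(rows), float(step), freqs_hz, octaves)


# ---------------------------------------------------------------- diagrams / histories


def write_diagram(path, comparison: StateComparison) -> None:
    with open(path, "w") as fh:
        fh.write("# strfnet diagram v1\n")
        fh.write(f"# recorded_neuron {comparison.recorded_neuron}\n")
        fh.write(
            "# columns label kind pre post passive_mean passive_sd "
            "behavioral_mean behavioral_sd solid_passive solid_behavioral\n"
        )
        for e in comparison.edges:
            fh.write(
                f"{e.label}\t{e.kind}\t{e.pre}\t{e.post}\t"
                f"{e.passive_mean:.4f}\t{e.passive_sd:.4f}\t"
                f"{e.behavioral_mean:.4f}\t{e.behavioral_sd:.4f}\t"
                f"{'solid' if e.solid_passive else 'dashed'}\t"
                f"{'solid' if e.solid_behavioral else 'dashed'}\n"
            )


def write_history(path, result) -> None:
    with open(path, "w") as fh:
        fh.write("# strfnet history v1\n")
        fh.write("# columns generation best_cost median_cost\n")
        for g, (b, m) in enumerate(zip(result.history_best, result.history_median)):
            fh.write(f"{g}\t{float(b)!r}\t{float(m)!r}\n")
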