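"""Readers and writers for spike-sorted event data.

Two on-disk dialects are supported:

* the legacy paired ``.res``/``.clu`` text format produced by classic
  spike-sorting pipelines — one integer spike time per ``.res`` line, and a
  ``.clu`` file whose first line is the number of clusters followed by one
  cluster ID per spike (clusters 0 and 1 conventionally hold noise and
  artifact events);
* a plain delimited table with columns ``time_tick`` and ``neuron_id``.

Neuron classification (pyramidal / interneuron / other, recording region,
shank) is read from a separate delimited table.  All times are integer sample
ticks; at the usual 20 kHz recording rate one tick is 0.05 ms.  Conversion to
milliseconds happens only at presentation boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO, Union

import numpy as np

__all__ = [
    "CELL_CLASSES",
    "REGIONS",
    "FormatError",
    "NeuronInfo",
    "SpikeDataset",
    "read_res_clu",
    "read_spike_table",
    "read_neuron_table",
    "write_spike_table",
    "write_res_clu",
    "write_neuron_table",
    "ms_to_ticks",
    "ticks_to_ms",
]

CELL_CLASSES = ("pyramidal", "interneuron", "other", "unknown")
REGIONS = ("pfc", "ca1", "unknown")

Source = Union[str, Path, TextIO]


class FormatError(ValueError):
    """Raised when an input file does not conform to its dialect."""


def ms_to_ticks(ms: float, sample_rate: float = 20000.0) -> int:
    """Convert milliseconds to the nearest integer sample tick."""
    return int(round(ms * sample_rate / 1000.0))


def ticks_to_ms(ticks: float, sample_rate: float = 20000.0) -> float:
    """Convert sample ticks to milliseconds."""
    return ticks * 1000.0 / sample_rate


@dataclass(frozen=True)
class NeuronInfo:
    """Classification record for one sorted unit.

    ``id`` is the cluster/unit ID as it appears in the spike stream (cluster
    IDs 0 and 1 from ``.clu`` files are permitted, since readers keep them by
    default).  ``cell_class`` and ``region`` are restricted vocabularies.
    """

    id: int
    cell_class: str = "unknown"
    region: str = "unknown"
    shank: int | None = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"neuron id must be non-negative, got {self.id}")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(
                f"unknown cell_class {self.cell_class!r}; "
                f"allowed: {', '.join(CELL_CLASSES)}"
            )
        if self.region not in REGIONS:
            raise ValueError(
                f"unknown region {self.region!r}; allowed: {', '.join(REGIONS)}"
            )
        if self.shank is not None and self.shank < 0:
            raise ValueError(f"shank must be non-negative, got {self.shank}")


@dataclass
class SpikeDataset:
    """Spike-sorted events: parallel time/ID arrays plus neuron metadata.

    ``spiket`` holds event times in integer sample ticks, non-decreasing;
    ``spikeind`` the matching neuron IDs.  Use :meth:`from_events` to build a
    dataset from unsorted events (ties keep input order).
    """

    spiket: np.ndarray
    spikeind: np.ndarray
    sample_rate: float = 20000.0
    neurons: dict[int, NeuronInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spiket = np.asarray(self.spiket, dtype=np.int64)
        self.spikeind = np.asarray(self.spikeind, dtype=np.int64)
        if self.spiket.ndim != 1 or self.spiket.shape != self.spikeind.shape:
            raise ValueError(
                "spiket and spikeind must be 1-D arrays of equal length "
                f"(got {self.spiket.shape} and {self.spikeind.shape})"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.spiket.size > 1 and np.any(np.diff(self.spiket) < 0):
            raise ValueError(
                "spike times must be non-decreasing; use SpikeDataset.from_events"
            )

    @classmethod
    def from_events(
        cls,
        spiket: Iterable[int],
        spikeind: Iterable[int],
        sample_rate: float = 20000.0,
        neurons: Mapping[int, NeuronInfo] | None = None,
    ) -> "SpikeDataset":
        """Build a dataset, stably sorting events by time."""
        t = np.asarray(list(spiket) if not isinstance(spiket, np.ndarray) else spiket,
                       dtype=np.int64)
        i = np.asarray(list(spikeind) if not isinstance(spikeind, np.ndarray) else spikeind,
                       dtype=np.int64)
        if t.shape != i.shape:
            raise ValueError("spiket and spikeind must have equal length")
        order = np.argsort(t, kind="stable")
        return cls(t[order], i[order], sample_rate, dict(neurons or {}))

    def __len__(self) -> int:
        return int(self.spiket.size)

    @property
    def n_spikes(self) -> int:
        return int(self.spiket.size)

    @property
    def tick_ms(self) -> float:
        """Duration of one sample tick in milliseconds."""
        return 1000.0 / self.sample_rate

    def neuron_info(self, neuron_id: int) -> NeuronInfo:
        """Metadata for ``neuron_id``, defaulting to an 'unknown' entry."""
        info = self.neurons.get(int(neuron_id))
        if info is None:
            info = NeuronInfo(id=int(neuron_id))
        return info

    def select(
        self,
        cell_class: str | None = None,
        region: str | None = None,
        neuron_ids: Iterable[int] | None = None,
    ) -> "SpikeDataset":
        """Subset of the dataset restricted by class, region and/or IDs."""
        present = np.unique(self.spikeind)
        allowed = set(int(n) for n in present)
        if neuron_ids is not None:
            allowed &= set(int(n) for n in neuron_ids)
        if cell_class is not None:
            allowed = {n for n in allowed if self.neuron_info(n).cell_class == cell_class}
        if region is not None:
            allowed = {n for n in allowed if self.neuron_info(n).region == region}
        mask = np.isin(self.spikeind, sorted(allowed))
        return SpikeDataset(
            self.spiket[mask], self.spikeind[mask], self.sample_rate, dict(self.neurons)
        )


def _open_text(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def _read_int_lines(source: Source, name: str) -> list[int]:
    fh, close = _open_text(source)
    values: list[int] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(int(token))
            except ValueError:
                raise FormatError(
                    f"{name}: non-integer token {token!r} on line {lineno}"
                ) from None
    finally:
        if close:
            fh.close()
    return values


def read_res_clu(
    res_source: Source,
    clu_source: Source,
    sample_rate: float = 20000.0,
    neurons: Mapping[int, NeuronInfo] | None = None,
    drop_noise_clusters: bool = False,
) -> SpikeDataset:
    """Read a paired ``.res``/``.clu`` file into a :class:`SpikeDataset`.

    Cluster IDs are used verbatim as neuron IDs (no renumbering).  The
    original recordings never established whether clusters 0 and 1 (noise and
    artifact by convention) should be excluded before analysis, so they are
    kept by default; pass ``drop_noise_clusters=True`` to discard them.
    """
    times = _read_int_lines(res_source, ".res")
    clu = _read_int_lines(clu_source, ".clu")
    if len(clu) != len(times) + 1:
        raise FormatError(
            f".clu must have one header line plus one ID per spike: "
            f".res has {len(times)} lines, .clu has {len(clu)}"
        )
    if any(t < 0 for t in times):
        raise FormatError(".res: spike times must be non-negative")
    ids = clu[1:]
    t = np.asarray(times, dtype=np.int64)
    i = np.asarray(ids, dtype=np.int64)
    if drop_noise_clusters:
        keep = i >= 2
        t, i = t[keep], i[keep]
    return SpikeDataset.from_events(t, i, sample_rate=sample_rate, neurons=neurons)


_DELIMS = (",", "\t", ";")


def _tokenize(line: str) -> list[str]:
    for d in _DELIMS:
        if d in line:
            return [tok.strip() for tok in line.split(d)]
    return line.split()


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_spike_table(
    source: Source,
    sample_rate: float = 20000.0,
    neurons: Mapping[int, NeuronInfo] | None = None,
) -> SpikeDataset:
    """Read a delimited spike table (columns ``time_tick``, ``neuron_id``).

    The header row is optional; without one the first two columns are taken
    as time and neuron ID.  Duplicate times are retained in input order.
    """
    fh, close = _open_text(source)
    try:
        lines = [ln for ln in (raw.strip() for raw in fh) if ln]
    finally:
        if close:
            fh.close()
    if not lines:
        return SpikeDataset.from_events([], [], sample_rate=sample_rate, neurons=neurons)
    header = _tokenize(lines[0])
    t_col, i_col = 0, 1
    start = 0
    if not all(_is_int(tok) for tok in header):
        names = [tok.lower() for tok in header]
        if "time_tick" not in names or "neuron_id" not in names:
            raise FormatError(
                "spike table header must contain columns "
                f"'time_tick' and 'neuron_id'; got {header}"
            )
        t_col, i_col = names.index("time_tick"), names.index("neuron_id")
        start = 1
    times: list[int] = []
    ids: list[int] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        toks = _tokenize(line)
        if len(toks) <= max(t_col, i_col):
            raise FormatError(f"spike table: missing column on line {lineno}")
        if not (_is_int(toks[t_col]) and _is_int(toks[i_col])):
            raise FormatError(f"spike table: non-integer value on line {lineno}")
        times.append(int(toks[t_col]))
        ids.append(int(toks[i_col]))
    return SpikeDataset.from_events(times, ids, sample_rate=sample_rate, neurons=neurons)


def write_spike_table(
    dataset: SpikeDataset, sink: Source, delimiter: str = "\t", header: bool = True
) -> None:
    """Write a dataset as a delimited spike table (round-trips exactly)."""
    fh, close = _open_text(sink, "w")
    try:
        if header:
            fh.write(f"time_tick{delimiter}neuron_id\n")
        for t, i in zip(dataset.spiket.tolist(), dataset.spikeind.tolist()):
            fh.write(f"{t}{delimiter}{i}\n")
    finally:
        if close:
            fh.close()


def write_res_clu(dataset: SpikeDataset, res_sink: Source, clu_sink: Source) -> None:
    """Write a dataset as paired ``.res``/``.clu`` text files."""
    fh, close = _open_text(res_sink, "w")
    try:
        for t in dataset.spiket.tolist():
            fh.write(f"{t}\n")
    finally:
        if close:
            fh.close()
    fh, close = _open_text(clu_sink, "w")
    try:
        n_clusters = int(np.unique(dataset.spikeind).size)
        fh.write(f"{n_clusters}\n")
        for i in dataset.spikeind.tolist():
            fh.write(f"{i}\n")
    finally:
        if close:
            fh.close()


def read_neuron_table(source: Source) -> dict[int, NeuronInfo]:
    """Read a neuron classification table.

    Columns: ``id``, ``cell_class`` and optionally ``region``, ``shank``
    (header optional, positional otherwise).  Class and region tokens are
    validated strictly against the allowed vocabularies.
    """
    fh, close = _open_text(source)
    try:
        lines = [ln for ln in (raw.strip() for raw in fh) if ln]
    finally:
        if close:
            fh.close()
    if not lines:
        return {}
    cols = {"id": 0, "cell_class": 1, "region": 2, "shank": 3}
    start = 0
    first = _tokenize(lines[0])
    if first and not _is_int(first[0]):
        names = [tok.lower() for tok in first]
        if "id" not in names or "cell_class" not in names:
            raise FormatError(
                f"neuron table header must contain 'id' and 'cell_class'; got {first}"
            )
        cols = {name: names.index(name) for name in names}
        start = 1
    table: dict[int, NeuronInfo] = {}
    for lineno, line in enumerate(lines[start:], start=start + 1):
        toks = _tokenize(line)
        try:
            nid = int(toks[cols["id"]])
            cls_tok = toks[cols["cell_class"]]
        except (IndexError, ValueError):
            raise FormatError(f"neuron table: bad row on line {lineno}") from None
        region = "unknown"
        if "region" in cols and cols["region"] < len(toks) and toks[cols["region"]]:
            region = toks[cols["region"]]
        shank: int | None = None
        if "shank" in cols and cols["shank"] < len(toks) and toks[cols["shank"]]:
            if not _is_int(toks[cols["shank"]]):
                raise FormatError(f"neuron table: non-integer shank on line {lineno}")
            shank = int(toks[cols["shank"]])
        table[nid] = NeuronInfo(id=nid, cell_class=cls_tok, region=region, shank=shank)
    return table


def write_neuron_table(
    neurons: Mapping[int, NeuronInfo], sink: Source, delimiter: str = "\t"
) -> None:
    fh, close = _open_text(sink, "w")
    try:
        fh.write(delimiter.join(("id", "cell_class", "region", "shank")) + "\n")
        for nid in sorted(neurons):
            info = neurons[nid]
            shank = "" if info.shank is None else str(info.shank)
            fh.write(delimiter.join((str(info.id), info.cell_class, info.region, shank)) + "\n")
    finally:
        if close:
            fh.close()
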