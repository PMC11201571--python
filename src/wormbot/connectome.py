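"""Connectome data model, file I/O, validation, and synthetic generation.

The wiring diagram is three-layered (sensory, interneuron, motor) with
signed, weighted chemical synapses.  Files arrive as a ``neurons.csv`` +
``synapses.csv`` pair (or a single JSON mirror); multiple synaptic contacts
between the same neuron pair are kept as distinct records because source
weights are per-contact.  A seeded synthetic generator produces download-free
feed-forward connectomes with explicit sensory->inter->motor motifs for
tests and fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NeuronRecord",
    "SynapseRecord",
    "Connectome",
    "GeneExpressionTable",
    "ChannelGeneMap",
    "Motif",
    "load_connectome",
    "write_connectome",
    "load_gene_expression",
    "load_channel_gene_map",
    "generate_synthetic_connectome",
    "infer_neuron_class",
    "SchemaError",
    "IntegrityError",
    "ValidationError",
]

NEURON_CLASSES = ("sensory", "interneuron", "motor")

#: canonical C. elegans name prefixes used when a file lacks class labels;
#: longest-prefix match wins, unknown names fall back to interneuron.
DEFAULT_CLASS_PREFIXES: dict[str, str] = {
    # sensory
    **{p: "sensory" for p in (
        "ASH", "ASE", "ASG", "ASI", "ASJ", "ASK", "ADE", "ADF", "ADL", "AFD",
        "AWA", "AWB", "AWC", "ALM", "AVM", "PLM", "PVM", "ALN", "PLN", "AQR",
        "PQR", "CEP", "OLQ", "OLL", "IL1", "IL2", "PDE", "PHA", "PHB", "PHC",
        "URX", "URY", "URB", "BAG", "FLP", "SDQ",
    )},
    # motor
    **{p: "motor" for p in (
        "DA", "DB", "DD", "VA", "VB", "VC", "VD", "AS", "PDA", "PDB",
        "RMD", "RMB", "RME", "RMF", "RMG", "RMH", "SMB", "SMD", "SIA", "SIB",
        "URA", "HSN", "VSN",
    )},
}


class SchemaError(ValueError):
    """A file is missing required columns/fields."""


class IntegrityError(ValueError):
    """An edge references a neuron absent from the neuron set."""


class ValidationError(ValueError):
    """A record violates a domain invariant (sign, range, duplicate name)."""


def normalize_name(name: str) -> str:
    return str(name).strip().upper()


def infer_neuron_class(
    name: str, overrides: Optional[dict[str, str]] = None
) -> tuple[str, bool]:
    """Classify a neuron by canonical name prefix.

    Returns ``(neuron_class, known)`` where ``known`` is False when the name
    matched no prefix and the interneuron default was used.
    """
    table = dict(DEFAULT_CLASS_PREFIXES)
    if overrides:
        table.update({normalize_name(k): v for k, v in overrides.items()})
    name = normalize_name(name)
    best = ""
    for prefix, cls in table.items():
        if name.startswith(prefix) and len(prefix) > len(best):
            best, found = prefix, cls
    if best:
        return found, True
    return "interneuron", False


@dataclass
class NeuronRecord:
    name: str
    neuron_class: str
    #: optional per-neuron parameter overrides (see wormbot.membrane.NeuronParams)
    params: Optional[object] = None

    def __post_init__(self) -> None:
        self.name = normalize_name(self.name)
        if self.neuron_class not in NEURON_CLASSES:
            raise ValidationError(
                f"neuron {self.name!r}: class {self.neuron_class!r} "
                f"not in {NEURON_CLASSES}"
            )


@dataclass
class SynapseRecord:
    pre: str
    post: str
    polarity: int  # +1 excitatory, -1 inhibitory
    weight: float  # dimensionless conductance increment, > 0
    tau: float = 10.0  # conductance decay constant, ms

    def __post_init__(self) -> None:
        self.pre = normalize_name(self.pre)
        self.post = normalize_name(self.post)
        self.polarity = int(self.polarity)
        if self.polarity not in (+1, -1):
            raise ValidationError(
                f"synapse {self.pre}->{self.post}: polarity {self.polarity} "
                "must be +1 or -1"
            )
        if not self.weight > 0:
            raise ValidationError(
                f"synapse {self.pre}->{self.post}: weight {self.weight} must be > 0"
            )
        if not self.tau > 0:
            raise ValidationError(
                f"synapse {self.pre}->{self.post}: tau {self.tau} must be > 0"
            )


@dataclass
class Connectome:
    neurons: list[NeuronRecord] = field(default_factory=list)
    synapses: list[SynapseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.neurons:
            raise ValidationError("a connectome needs at least one neuron")
        names = [n.name for n in self.neurons]
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise ValidationError(f"duplicate neuron name {name!r}")
            seen.add(name)
        for i, syn in enumerate(self.synapses):
            for end in (syn.pre, syn.post):
                if end not in seen:
                    raise IntegrityError(
                        f"synapse row {i} references unknown neuron {end!r}"
                    )

    @property
    def neuron_names(self) -> list[str]:
        return [n.name for n in self.neurons]

    def by_class(self, neuron_class: str) -> list[str]:
        return [n.name for n in self.neurons if n.neuron_class == neuron_class]

    def neuron(self, name: str) -> NeuronRecord:
        name = normalize_name(name)
        for n in self.neurons:
            if n.name == name:
                return n
        raise KeyError(name)

    def edge_multiset(self) -> list[tuple]:
        """Sorted (pre, post, polarity, weight, tau) tuples, for round trips."""
        return sorted(
            (s.pre, s.post, s.polarity, round(s.weight, 12), round(s.tau, 12))
            for s in self.synapses
        )


# ---------------------------------------------------------------------------
# file I/O

_NEURON_COLS = {"name", "class"}
_SYNAPSE_COLS = {"pre", "post", "polarity", "weight"}


def _neurons_from_frame(
    df: pd.DataFrame, class_overrides: Optional[dict[str, str]]
) -> list[NeuronRecord]:
    if "name" not in df.columns:
        raise SchemaError(f"neurons table missing column 'name'; has {list(df.columns)}")
    records = []
    has_class = "class" in df.columns
    for _, row in df.iterrows():
        if has_class and isinstance(row["class"], str) and row["class"].strip():
            cls = row["class"].strip().lower()
        else:
            cls, known = infer_neuron_class(row["name"], class_overrides)
            if not known:
                import warnings

                warnings.warn(
                    f"neuron {row['name']!r}: unknown name prefix, "
                    "defaulting to interneuron",
                    stacklevel=3,
                )
        records.append(NeuronRecord(name=row["name"], neuron_class=cls))
    return records


def _synapses_from_frame(df: pd.DataFrame, default_tau: float) -> list[SynapseRecord]:
    missing = _SYNAPSE_COLS - set(df.columns)
    if missing:
        raise SchemaError(f"synapses table missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        tau = row["tau"] if "tau" in df.columns and pd.notna(row.get("tau")) else default_tau
        records.append(
            SynapseRecord(
                pre=row["pre"],
                post=row["post"],
                polarity=int(row["polarity"]),
                weight=float(row["weight"]),
                tau=float(tau),
            )
        )
    return records


def load_connectome(
    path: str | Path,
    format: str = "csv",
    default_tau: float = 10.0,
    class_overrides: Optional[dict[str, str]] = None,
) -> Connectome:
    """Load and validate a connectome.

    ``csv``: *path* is a directory holding ``neurons.csv`` (name, class) and
    ``synapses.csv`` (pre, post, polarity, weight[, tau]).  ``json``: *path*
    is a single file mirroring those fields.  Duplicate edges are kept as
    distinct synaptic contacts.
    """
    path = Path(path)
    if format == "csv":
        nfile, sfile = path / "neurons.csv", path / "synapses.csv"
        for f in (nfile, sfile):
            if not f.exists():
                raise FileNotFoundError(f)
        neurons = _neurons_from_frame(pd.read_csv(nfile), class_overrides)
        synapses = _synapses_from_frame(pd.read_csv(sfile), default_tau)
    elif format == "json":
        data = json.loads(Path(path).read_text())
        for key in ("neurons", "synapses"):
            if key not in data:
                raise SchemaError(f"JSON connectome missing key {key!r}")
        neurons = _neurons_from_frame(pd.DataFrame(data["neurons"]), class_overrides)
        synapses = _synapses_from_frame(pd.DataFrame(data["synapses"]), default_tau)
    else:
        raise ValueError(f"unknown format {format!r}")
    return Connectome(neurons=neurons, synapses=synapses)


def write_connectome(conn: Connectome, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    neurons = pd.DataFrame(
        {"name": [n.name for n in conn.neurons],
         "class": [n.neuron_class for n in conn.neurons]}
    )
    synapses = pd.DataFrame(
        {"pre": [s.pre for s in conn.synapses],
         "post": [s.post for s in conn.synapses],
         "polarity": [s.polarity for s in conn.synapses],
         "weight": [s.weight for s in conn.synapses],
         "tau": [s.tau for s in conn.synapses]}
    )
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        neurons.to_csv(path / "neurons.csv", index=False)
        synapses.to_csv(path / "synapses.csv", index=False)
    elif format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(
            {"neurons": neurons.to_dict(orient="records"),
             "synapses": synapses.to_dict(orient="records")}, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene expression

@dataclass
class GeneExpressionTable:
    """Neuron x gene table of non-negative expression levels."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate neuron rows {dupes}")
        bad = np.argwhere(df.values < 0)
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"negative expression at (neuron {df.index[r]!r}, "
                f"gene {df.columns[c]!r}): {df.values[r, c]}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.table.columns)

    @property
    def neurons(self) -> list[str]:
        return list(self.table.index)

    def level(self, neuron: str, gene: str) -> float:
        return float(self.table.loc[normalize_name(neuron), gene])


def load_gene_expression(path: str | Path) -> GeneExpressionTable:
    df = pd.read_csv(path, index_col=0)
    df.index = [normalize_name(n) for n in df.index]
    return GeneExpressionTable(df)


@dataclass
class ChannelGeneMap:
    """Mapping from channel kind {K, Na, Ca, leak} to contributing genes."""

    mapping: dict[str, list[str]]

    CHANNELS = ("K", "Na", "Ca", "leak")

    def __post_init__(self) -> None:
        unknown = set(self.mapping) - set(self.CHANNELS)
        if unknown:
            raise ValidationError(f"unknown channel kind(s) {sorted(unknown)}")

    def check_against(self, expr: GeneExpressionTable) -> None:
        known = set(expr.genes)
        for channel, genes in self.mapping.items():
            for gene in genes:
                if gene not in known:
                    raise ValidationError(
                        f"channel {channel!r}: gene {gene!r} absent from "
                        "the expression table"
                    )


def load_channel_gene_map(path: str | Path) -> ChannelGeneMap:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError("channel->gene map must be a JSON object")
    return ChannelGeneMap({k: list(v) for k, v in data.items()})


# ---------------------------------------------------------------------------
# synthetic generation

@dataclass
class Motif:
    """An explicit two-hop sensory->inter->motor path added on top of the
    random feed-forward background, through a dedicated interneuron."""

    sensory: int | str
    motor: int | str
    polarity: int = +1
    weight: float = 2.0
    tau: float = 10.0


def generate_synthetic_connectome(
    n_sensory: int,
    n_inter: int,
    n_motor: int,
    motifs: Sequence[Motif] = (),
    seed: int = 0,
    p_feedforward: float = 0.3,
    sensory_names: Optional[Sequence[str]] = None,
    motor_names: Optional[Sequence[str]] = None,
    weight_range: tuple[float, float] = (0.2, 1.0),
    tau: float = 10.0,
) -> Connectome:
    """Generate a deterministic three-layer synthetic connectome.

    Background wiring is feed-forward (every sensory->inter and inter->motor
    pair is a candidate edge drawn with probability ``p_feedforward``);
    requested motifs add explicit strong two-hop paths through dedicated
    interneurons, emulating the stimulus->response circuits the discovery
    sweep looks for.  Identical arguments (including ``seed``) give
    byte-identical connectomes.
    """
    if min(n_sensory, n_inter, n_motor) < 1:
        raise ValueError("neuron counts must be >= 1")
    rng = np.random.default_rng(seed)

    def _names(given, n, prefix):
        if given is not None:
            if len(given) != n:
                raise ValueError(f"{prefix}: expected {n} names, got {len(given)}")
            return [normalize_name(x) for x in given]
        return [f"{prefix}{i:02d}" for i in range(n)]

    sens = _names(sensory_names, n_sensory, "SN")
    inter = [f"IN{i:02d}" for i in range(n_inter)]
    mot = _names(motor_names, n_motor, "MN")

    neurons = (
        [NeuronRecord(n, "sensory") for n in sens]
        + [NeuronRecord(n, "interneuron") for n in inter]
        + [NeuronRecord(n, "motor") for n in mot]
    )
    synapses: list[SynapseRecord] = []
    lo_w, hi_w = weight_range
    for s in sens:
        for i in inter:
            if rng.random() < p_feedforward:
                synapses.append(SynapseRecord(
                    s, i, +1, float(rng.uniform(lo_w, hi_w)), tau))
    for i in inter:
        for m in mot:
            if rng.random() < p_feedforward:
                pol = +1 if rng.random() < 0.8 else -1
                synapses.append(SynapseRecord(
                    i, m, pol, float(rng.uniform(lo_w, hi_w)), tau))

    def _resolve(ref: int | str, pool: list[str], layer: str) -> str:
        if isinstance(ref, str):
            name = normalize_name(ref)
            if name not in pool:
                raise ValueError(f"motif references unknown {layer} neuron {ref!r}")
            return name
        if not 0 <= ref < len(pool):
            raise ValueError(
                f"motif references out-of-range {layer} index {ref} "
                f"(have {len(pool)})"
            )
        return pool[ref]

    for k, motif in enumerate(motifs):
        s = _resolve(motif.sensory, sens, "sensory")
        m = _resolve(motif.motor, mot, "motor")
        relay = f"IM{k:02d}"
        neurons.append(NeuronRecord(relay, "interneuron"))
        synapses.append(SynapseRecord(s, relay, +1, motif.weight, motif.tau))
        synapses.append(SynapseRecord(relay, m, motif.polarity, motif.weight, motif.tau))

    return Connectome(neurons=neurons, synapses=synapses)
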