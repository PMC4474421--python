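"""Synthetic curated-interaction databases and qPCR dose-response data.

Curated drug-gene interaction databases are proprietary, and raw qPCR
plate data is rarely deposited; these generators produce structurally
faithful stand-ins with complete ground truth, so every pipeline stage
can be tested against known answers.

The network generator emulates a two-layer signed regulatory database:
compounds attach to regulator hubs with fixed per-regulator weights
(producing the skewed, hub-dominated cluster sizes seen in curated
compound-regulator networks), regulators attach uniformly to enzymes, and
edge signs are sampled from a {+1, -1, 0} mixture.  Explicit
compound -> regulator -> enzyme paths can be planted with chosen signs;
random edges never duplicate or contradict a planted edge, so the planted
truth stays unambiguous.

The qPCR generator emulates a vehicle + dose design with replicate wells:
Ct values are the baseline minus a per-dose log2 effect plus Gaussian
noise on the cycle (log2 expression) scale, the standard qPCR error
model.  The default effect profile rises with dose and flattens at the
middle doses (a saturating dose response).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ParseError
from .io import Entity, InteractionRecord, InteractionTable
from .qpcr import ExpressionDataset, Observation

__all__ = [
    "NetworkSimConfig",
    "QpcrSimConfig",
    "NetworkGroundTruth",
    "generate_interaction_db",
    "generate_qpcr",
    "read_network_config",
    "read_qpcr_config",
]


@dataclass(frozen=True)
class NetworkSimConfig:
    """Parameters of the synthetic two-layer interaction database.

    Defaults approximate the scale of a curated compound-regulator
    network: a few hundred compounds attaching to ~15 regulator hubs
    (Zipf-like attachment weights give a heavy-tailed cluster-size
    ranking), each regulator acting on a couple of the ~10 CYP enzymes.
    ``sign_probs`` are the probabilities of +1, -1 and 0 (unknown) edge
    signs; curated databases carry a small direction-less fraction.
    """

    n_compounds: int = 300
    n_regulators: int = 15
    n_enzymes: int = 10
    mean_compound_degree: float = 2.9
    mean_regulator_enzyme_degree: float = 2.0
    hub_weights: tuple[float, ...] | None = None  # default: Zipf 1/(rank+1)
    sign_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)
    planted_paths: tuple[tuple[object, object, object, int, int], ...] = ()
    compound_names: tuple[str, ...] | None = None
    regulator_names: tuple[str, ...] | None = None
    enzyme_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_regulators, self.n_enzymes) < 0:
            raise ArgumentError("entity counts must be non-negative")
        if self.mean_compound_degree < 0 or self.mean_regulator_enzyme_degree < 0:
            raise ArgumentError("mean degrees must be non-negative")
        if len(self.sign_probs) != 3 or any(p < 0 for p in self.sign_probs):
            raise ArgumentError("sign_probs must be three non-negative numbers")
        if abs(sum(self.sign_probs) - 1.0) > 1e-12:
            raise ArgumentError("sign_probs must sum to 1")
        if self.hub_weights is not None:
            if len(self.hub_weights) != self.n_regulators:
                raise ArgumentError(
                    "hub_weights must have one weight per regulator"
                )
            if any(w <= 0 for w in self.hub_weights):
                raise ArgumentError("hub_weights must be positive")
        for names, count, label in (
            (self.compound_names, self.n_compounds, "compound"),
            (self.regulator_names, self.n_regulators, "regulator"),
            (self.enzyme_names, self.n_enzymes, "enzyme"),
        ):
            if names is not None and len(names) != count:
                raise ArgumentError(f"need exactly {count} {label} names")


@dataclass(frozen=True)
class QpcrSimConfig:
    """Parameters of the synthetic qPCR dose-response experiment.

    Defaults mirror a vehicle + five-dose design run in triplicate.
    ``log2_effects`` is the per-dose shift of log2 expression relative to
    vehicle (one unit = one PCR cycle = a twofold change); the default
    profile rises and saturates across the mid doses.  ``noise_sd`` is
    the SD of Gaussian Ct noise in cycles.
    """

    doses: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)
    n_replicates: int = 3
    baseline_ct: float = 24.0
    log2_effects: tuple[float, ...] = (0.0, 0.5, 1.0, 1.8, 2.0, 2.1)
    noise_sd: float = 0.25
    cell_line: str = "HeLa"
    gene: str = "CYP19A1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.doses)) != len(self.doses):
            raise ArgumentError("doses must be distinct")
        if 0.0 not in self.doses:
            raise ArgumentError("doses must include the vehicle (0)")
        if len(self.log2_effects) != len(self.doses):
            raise ArgumentError("log2_effects must parallel doses")
        if self.log2_effects[self.doses.index(0.0)] != 0.0:
            raise ArgumentError("the vehicle (dose 0) log2 effect must be 0")
        if self.n_replicates < 2:
            raise ArgumentError("n_replicates must be >= 2")
        if self.noise_sd <= 0:
            raise ArgumentError("noise_sd must be > 0")
        if self.baseline_ct <= 0:
            raise ArgumentError("baseline_ct must be positive")


@dataclass
class NetworkGroundTruth:
    """Complete truth for one generated database.

    ``predictions`` holds, for every compound-enzyme pair connected by at
    least one two-step path, the aggregate net sign (0 when paths
    disagree or contain an unknown edge) and the number of paths —
    exactly what the discovery pipeline should recover.  ``planted``
    restates the rows for the explicitly planted paths.
    """

    predictions: pd.DataFrame  # columns: compound, enzyme, net_sign, n_paths
    planted: list[tuple[str, str, int]]


def _default_names(prefix: str, n: int) -> tuple[str, ...]:
    width = max(2, len(str(n)))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


def _resolve(ref: object, ids: Sequence[str], label: str) -> str:
    if isinstance(ref, (int, np.integer)):
        if not 0 <= int(ref) < len(ids):
            raise ArgumentError(
                f"planted path {label} index {ref} out of range [0, {len(ids)})"
            )
        return ids[int(ref)]
    if ref in ids:
        return str(ref)
    raise ArgumentError(f"planted path references unknown {label} {ref!r}")


def generate_interaction_db(
    cfg: NetworkSimConfig,
) -> tuple[InteractionTable, NetworkGroundTruth]:
    """Generate a signed two-layer interaction database with ground truth.

    Deterministic: the same config (including seed) yields an identical
    table and truth on every run.
    """
    rng = np.random.default_rng(cfg.seed)

    compound_ids = cfg.compound_names or _default_names("C", cfg.n_compounds)
    regulator_ids = cfg.regulator_names or _default_names("R", cfg.n_regulators)
    enzyme_ids = cfg.enzyme_names or _default_names("E", cfg.n_enzymes)

    entities = {}
    for ids, role in (
        (compound_ids, "compound"),
        (regulator_ids, "regulator"),
        (enzyme_ids, "enzyme"),
    ):
        for eid in ids:
            if eid in entities:
                raise ArgumentError(f"duplicate entity id {eid!r} across roles")
            entities[eid] = Entity(id=eid, name=eid, role=role)

    cr_edges: dict[tuple[str, str], int] = {}  # compound -> regulator
    re_edges: dict[tuple[str, str], int] = {}  # regulator -> enzyme
    for path in cfg.planted_paths:
        c_ref, r_ref, e_ref, s1, s2 = path
        c = _resolve(c_ref, compound_ids, "compound")
        r = _resolve(r_ref, regulator_ids, "regulator")
        e = _resolve(e_ref, enzyme_ids, "enzyme")
        if int(s1) not in (-1, 0, 1) or int(s2) not in (-1, 0, 1):
            raise ArgumentError(f"planted path signs must be in {{-1,0,1}}: {path}")
        for store, key, sign in ((cr_edges, (c, r), int(s1)), (re_edges, (r, e), int(s2))):
            if key in store and store[key] != sign:
                raise ArgumentError(
                    f"planted paths assign conflicting signs to edge {key}"
                )
            store[key] = sign

    signs = np.array([+1, -1, 0])
    sign_p = np.asarray(cfg.sign_probs, dtype=float)

    if cfg.hub_weights is not None:
        weights = np.asarray(cfg.hub_weights, dtype=float)
    else:
        weights = 1.0 / (np.arange(cfg.n_regulators) + 1.0)

    # compound -> regulator layer: weighted attachment to hubs
    if cfg.n_regulators > 0:
        probs = weights / weights.sum()
        for c in compound_ids:
            taken = {r for (cc, r) in cr_edges if cc == c}
            free = [r for r in regulator_ids if r not in taken]
            if not free:
                continue
            deg = int(min(rng.poisson(cfg.mean_compound_degree), len(free)))
            if deg == 0:
                continue
            free_p = np.array([probs[regulator_ids.index(r)] for r in free])
            free_p /= free_p.sum()
            chosen = rng.choice(len(free), size=deg, replace=False, p=free_p)
            for idx in sorted(chosen):
                r = free[idx]
                cr_edges[(c, r)] = int(rng.choice(signs, p=sign_p))

    # regulator -> enzyme layer: uniform attachment
    if cfg.n_enzymes > 0:
        for r in regulator_ids:
            taken = {e for (rr, e) in re_edges if rr == r}
            free = [e for e in enzyme_ids if e not in taken]
            if not free:
                continue
            deg = int(min(rng.poisson(cfg.mean_regulator_enzyme_degree), len(free)))
            if deg == 0:
                continue
            chosen = rng.choice(len(free), size=deg, replace=False)
            for idx in sorted(chosen):
                e = free[idx]
                re_edges[(r, e)] = int(rng.choice(signs, p=sign_p))

    records = [
        InteractionRecord(source_id=c, target_id=r, sign=s, provenance="simulated")
        for (c, r), s in sorted(cr_edges.items())
    ] + [
        InteractionRecord(source_id=r, target_id=e, sign=s, provenance="simulated")
        for (r, e), s in sorted(re_edges.items())
    ]
    used = {eid for rec in records for eid in (rec.source_id, rec.target_id)}
    table = InteractionTable(
        entities={eid: ent for eid, ent in entities.items() if eid in used},
        records=records,
    )

    # Exhaustive two-step path truth, independent of the pipeline code:
    # every compound->enzyme path is compound->regulator->enzyme.
    out_of: dict[str, list[tuple[str, int]]] = {}
    for (r, e), s in re_edges.items():
        out_of.setdefault(r, []).append((e, s))
    path_signs: dict[tuple[str, str], list[int]] = {}
    for (c, r), s1 in cr_edges.items():
        for e, s2 in out_of.get(r, []):
            path_signs.setdefault((c, e), []).append(
                0 if s1 == 0 or s2 == 0 else s1 * s2
            )
    rows = []
    for (c, e), sgns in sorted(path_signs.items()):
        uniq = set(sgns)
        rows.append(
            {
                "compound": c,
                "enzyme": e,
                "net_sign": uniq.pop() if len(uniq) == 1 else 0,
                "n_paths": len(sgns),
            }
        )
    predictions = pd.DataFrame(
        rows, columns=["compound", "enzyme", "net_sign", "n_paths"]
    )

    planted = []
    by_pair = {(row["compound"], row["enzyme"]): row["net_sign"] for row in rows}
    for path in cfg.planted_paths:
        c = _resolve(path[0], compound_ids, "compound")
        e = _resolve(path[2], enzyme_ids, "enzyme")
        planted.append((c, e, int(by_pair[(c, e)])))

    return table, NetworkGroundTruth(predictions=predictions, planted=planted)


def generate_qpcr(cfg: QpcrSimConfig) -> ExpressionDataset:
    """Simulate Ct values for a vehicle + dose qPCR experiment.

    Ct(dose d, replicate r) = baseline_ct - log2_effect(d) + N(0, noise_sd);
    a positive log2 effect lowers the Ct (more transcript, earlier
    amplification).  Deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(cfg.doses), cfg.n_replicates))
    observations = [
        Observation(
            dose=dose,
            replicate=rep + 1,
            value=cfg.baseline_ct - effect + noise[i, rep],
        )
        for i, (dose, effect) in enumerate(zip(cfg.doses, cfg.log2_effects))
        for rep in range(cfg.n_replicates)
    ]
    return ExpressionDataset(
        cell_line=cfg.cell_line,
        gene=cfg.gene,
        observations=observations,
        value_kind="ct",
    )


# -- flat key-value config files -------------------------------------------
#
# Schema: one `key = value` per line, `#` starts a comment.  Lists are
# comma-separated; planted paths are `c:r:e:sign1:sign2` items separated
# by semicolons, where c/r/e are entity indices (0-based) or ids.


def _parse_kv(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"expected 'key = value', got {line!r}", line_number=i)
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _floats(s: str) -> tuple[float, ...]:
    return tuple(float(x) for x in s.split(",") if x.strip())


def _planted(s: str) -> tuple[tuple[object, object, object, int, int], ...]:
    paths = []
    for item in s.split(";"):
        item = item.strip()
        if not item:
            continue
        parts = [p.strip() for p in item.split(":")]
        if len(parts) != 5:
            raise ParseError(f"planted path needs 5 fields c:r:e:s1:s2, got {item!r}")
        refs = [int(p) if p.lstrip("+-").isdigit() else p for p in parts[:3]]
        paths.append((refs[0], refs[1], refs[2], int(parts[3]), int(parts[4])))
    return tuple(paths)


def read_network_config(path: str | Path, seed: int | None = None) -> NetworkSimConfig:
    kv = _parse_kv(path)
    kwargs: dict = {}
    for key in ("n_compounds", "n_regulators", "n_enzymes"):
        if key in kv:
            kwargs[key] = int(kv.pop(key))
    for key in ("mean_compound_degree", "mean_regulator_enzyme_degree"):
        if key in kv:
            kwargs[key] = float(kv.pop(key))
    if "hub_weights" in kv:
        kwargs["hub_weights"] = _floats(kv.pop("hub_weights"))
    if "sign_probs" in kv:
        kwargs["sign_probs"] = _floats(kv.pop("sign_probs"))
    if "planted_paths" in kv:
        kwargs["planted_paths"] = _planted(kv.pop("planted_paths"))
    for key in ("compound_names", "regulator_names", "enzyme_names"):
        if key in kv:
            kwargs[key] = tuple(x.strip() for x in kv.pop(key).split(","))
    if "seed" in kv:
        kwargs["seed"] = int(kv.pop("seed"))
    if seed is not None:
        kwargs["seed"] = seed
    if kv:
        raise ParseError(f"unknown network config keys: {sorted(kv)}")
    return NetworkSimConfig(**kwargs)


def read_qpcr_config(path: str | Path, seed: int | None = None) -> QpcrSimConfig:
    kv = _parse_kv(path)
    kwargs: dict = {}
    if "doses" in kv:
        kwargs["doses"] = _floats(kv.pop("doses"))
    if "log2_effects" in kv:
        kwargs["log2_effects"] = _floats(kv.pop("log2_effects"))
    for key in ("baseline_ct", "noise_sd"):
        if key in kv:
            kwargs[key] = float(kv.pop(key))
    if "n_replicates" in kv:
        kwargs["n_replicates"] = int(kv.pop("n_replicates"))
    for key in ("cell_line", "gene"):
        if key in kv:
            kwargs[key] = kv.pop(key)
    if "seed" in kv:
        kwargs["seed"] = int(kv.pop("seed"))
    if seed is not None:
        kwargs["seed"] = seed
    if kv:
        raise ParseError(f"unknown qPCR config keys: {sorted(kv)}")
    return QpcrSimConfig(**kwargs)
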