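"""Property evaluators pluggable into the inverse-design search.

Three evaluator families are provided:

* **fixture evaluator** — replays β_HRS values transcribed from published
  DFT tables, keyed by canonical structure key and frequency, so the search
  engine and contrast machinery are testable without quantum chemistry;
* **synthetic landscape** — a seeded structure-property model over the
  compound space with per-(group, fragment, state) base contributions,
  optional pairwise inter-site couplings, and a centrosymmetry-cancellation
  rule (formally centrosymmetric 28R structures get β = 0 unless a
  symmetry-breaking fragment is present), emulating the dominant physics of
  the real landscape: symmetry dominance and push-pull cooperativity;
* **external evaluator** — a file-based request/response contract that
  delegates β tensors to an external program and reduces them with the HRS
  invariants on pickup.

Evaluators are callables ``evaluate(state, assignment, frequency=0.0) -> β``.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemspace as cs
from . import nlo_tensor

__all__ = [
    "PaperRecord",
    "FixtureSet",
    "load_fixtures",
    "table_evaluator",
    "SyntheticLandscapeSpec",
    "synthetic_evaluator",
    "ExternalEvaluator",
    "write_request",
    "response_path_for",
    "FixtureError",
    "EvaluatorLookupError",
]

_FREQ_COLUMNS = {0.0: "beta_hrs_static", 0.653: "beta_hrs_0653", 1.165: "beta_hrs_1165"}
_TABLE_FILES = ("table1.csv", "table2.csv", "table3.csv", "section43.csv")

_DESCRIPTOR_FIELDS = (
    "phi_p", "pi_index", "lambda_exalt", "nics_zz1", "av1245", "av_min",
    "delta_eta", "delta_hl",
)


class FixtureError(ValueError):
    """Fixture file missing, malformed, or failing validation."""


class EvaluatorLookupError(LookupError):
    """No record for the requested structure key / frequency."""

    def __init__(self, key: str, frequency: float):
        super().__init__(f"no fixture record for {key!r} at {frequency} eV")
        self.key = key
        self.frequency = frequency


@dataclass(frozen=True)
class PaperRecord:
    """One fixture row: a structure in one state with its printed properties.

    β values are in a.u.; ``None`` marks unprinted cells.  Descriptor columns
    (ring strain Φ_p, conjugation index Π, aromaticity indices, HOMO-LUMO gap)
    are read-only metadata.  ``symmetry`` records the relaxed point group when
    stated (``Ci`` forces β = 0; printed "~0" cells are stored as exactly 0).
    """

    key: str
    state: str
    pattern: str
    beta_hrs: dict[float, float]
    symmetry: str = "unknown"
    provenance: str = ""
    descriptors: dict[str, float] = field(default_factory=dict)

    def beta_at(self, frequency: float) -> float:
        try:
            return self.beta_hrs[frequency]
        except KeyError:
            raise EvaluatorLookupError(self.key, frequency) from None


def _rounding_slack(value: float) -> float:
    """Half a unit in the last printed digit, assuming 3 significant figures."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value))) - 2
    return 0.5 * 10.0**exponent


class FixtureSet:
    """All packaged fixture rows, indexed by (key, provenance table)."""

    def __init__(self, records: list[PaperRecord],
                 contrast_tables: dict[str, pd.DataFrame]):
        self.records = records
        self.contrast_tables = contrast_tables
        self._by_key: dict[str, PaperRecord] = {}
        for r in records:
            # later tables never silently shadow earlier ones with a
            # conflicting beta; first occurrence wins for lookups
            self._by_key.setdefault(r.key, r)
        self._by_key_table = {(r.provenance, r.key): r for r in records}

    def __len__(self):
        return len(self.records)

    def __contains__(self, key: str):
        return key in self._by_key

    def get(self, key: str, table: str | None = None) -> PaperRecord:
        if table is not None:
            try:
                return self._by_key_table[(table, key)]
            except KeyError:
                raise EvaluatorLookupError(key, float("nan")) from None
        try:
            return self._by_key[key]
        except KeyError:
            raise EvaluatorLookupError(key, float("nan")) from None

    def beta(self, key: str, frequency: float = 0.0, table: str | None = None) -> float:
        return self.get(key, table).beta_at(frequency)


def _parse_table(path_or_buffer, name: str) -> list[PaperRecord]:
    df = pd.read_csv(path_or_buffer)
    required = {"key", "state", "symmetry", "provenance", "beta_hrs_static"}
    missing = required - set(df.columns)
    if missing:
        raise FixtureError(f"{name}: missing columns {sorted(missing)}")
    records = []
    errors = []
    for idx, row in df.iterrows():
        label = f"{name} row {idx + 2} ({row.get('key', '?')})"  # +2: header+1-based
        betas: dict[float, float] = {}
        for freq, col in _FREQ_COLUMNS.items():
            if col in df.columns and pd.notna(row[col]):
                v = float(row[col])
                if v < 0:
                    errors.append(f"{label}: negative beta {v} in {col}")
                    continue
                betas[freq] = v
        state = str(row["state"])
        if state not in cs.STATES:
            errors.append(f"{label}: unknown state {state!r}")
        symmetry = str(row["symmetry"])
        if symmetry == "Ci" and any(v != 0 for v in betas.values()):
            errors.append(f"{label}: symmetry Ci requires beta 0, got {betas}")
        descriptors = {
            f: float(row[f])
            for f in _DESCRIPTOR_FIELDS
            if f in df.columns and pd.notna(row[f])
        }
        records.append(
            PaperRecord(
                key=str(row["key"]),
                state=state,
                pattern=str(row.get("pattern", "")),
                beta_hrs=betas,
                symmetry=symmetry,
                provenance=str(row["provenance"]),
                descriptors=descriptors,
            )
        )
    if errors:
        raise FixtureError("fixture validation failed:\n  " + "\n  ".join(errors))
    return records


def _validate_table2_contrasts(records: list[PaperRecord], contrasts: pd.DataFrame):
    """Check every printed contrast cell against recomputation from the betas.

    Tolerance is 1% relative, widened by the slack that 3-significant-figure
    rounding of the two β operands propagates into the derived quantity, so
    the check is exactly as strict as the printed precision allows.
    """
    from . import contrast as ct

    by_key = {r.key: r for r in records if r.provenance == "table2"}
    errors = []
    for _, row in contrasts.iterrows():
        sub = row["substituent"]
        try:
            on26 = by_key[f"26R({sub})"].beta_at(0.0)
            on28m = by_key[f"28M({sub})"].beta_at(0.0)
            off = by_key[f"28R({sub})"].beta_at(0.0)
        except (KeyError, EvaluatorLookupError):
            errors.append(f"contrast row {sub}: missing state rows")
            continue
        for printed, on, kind in (
            (float(row["ratio_26R_28R"]), on26, "ratio"),
            (float(row["ratio_28M_28R"]), on28m, "ratio"),
            (float(row["diff_26R_28R"]), on26, "difference"),
            (float(row["diff_28M_28R"]), on28m, "difference"),
        ):
            pair = ct.SwitchPair(beta_on=on, beta_off=off)
            if kind == "ratio":
                recomputed, _ = ct.ratio_contrast(pair)
                # ratio error from input rounding, first order
                slack = abs(recomputed) * (
                    (_rounding_slack(on) / on if on else 0.0)
                    + (_rounding_slack(off) / off if off else 0.0)
                )
            else:
                recomputed = ct.difference_contrast(pair)
                slack = _rounding_slack(on) + _rounding_slack(off)
            tol = max(0.01 * abs(printed), slack)
            if abs(recomputed - printed) > tol:
                errors.append(
                    f"contrast row {sub} ({kind}): printed {printed:g}, "
                    f"recomputed {recomputed:g}, tol {tol:g}"
                )
    if errors:
        raise FixtureError("table2 contrast validation failed:\n  " + "\n  ".join(errors))


def load_fixtures(data_dir=None) -> FixtureSet:
    """Load and validate all packaged fixture tables.

    ``data_dir`` overrides the packaged CSV directory (used in tests).  Load
    aborts with a :class:`FixtureError` listing every violated row.
    """

    def _open(name: str):
        if data_dir is not None:
            p = Path(data_dir) / name
            if not p.exists():
                raise FixtureError(f"missing fixture file {p}")
            return p
        res = resources.files("hexanlo") / "data" / name
        if not res.is_file():
            raise FixtureError(f"missing packaged fixture {name}")
        return res.open("r")

    records: list[PaperRecord] = []
    for name in _TABLE_FILES:
        records.extend(_parse_table(_open(name), name))
    contrast_tables = {
        "table2": pd.read_csv(_open("table2_contrasts.csv")),
        "section4.3": pd.read_csv(_open("section43_contrasts.csv")),
    }
    _validate_table2_contrasts(records, contrast_tables["table2"])
    return FixtureSet(records, contrast_tables)


def table_evaluator(fixtures: FixtureSet | None = None):
    """Evaluator replaying fixture β values; raises on unknown structures.

    Returned callable: ``evaluate(state, assignment, frequency=0.0) -> β``.
    ``assignment`` may be a :class:`~hexanlo.chemspace.Assignment` or a
    ready-made canonical key string.
    """
    fx = fixtures if fixtures is not None else load_fixtures()

    def evaluate(state: str, assignment, frequency: float = 0.0) -> float:
        if isinstance(assignment, str):
            key = assignment
        else:
            key = cs.SwitchStructure(state, assignment).key
        if key not in fx:
            raise EvaluatorLookupError(key, frequency)
        return fx.beta(key, frequency)

    return evaluate


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    """Seeded synthetic β_HRS landscape over one pattern's compound space.

    β(state, assignment) = 0 if the centrosymmetry-cancellation rule applies,
    otherwise ``| Σ_g base(g, frag_g, state) + Σ_{g<h} coupling(...) |``.

    Base contributions are |N(0, base_scale)| per (group, fragment, state);
    couplings are N(0, coupling_scale) per (group pair, fragment pair, state).
    ``coupling_scale = 0`` gives an exactly additive (independent-site)
    landscape on which greedy site-by-site search is provably optimal.
    Default scales put single-structure β values in the 10²–10⁴ a.u. range of
    the tabulated hexaphyrins.
    """

    pattern: cs.SubstitutionPattern
    library: tuple[str, ...]
    seed: int = 0
    base_scale: float = 2000.0
    coupling_scale: float = 0.0
    states: tuple[str, ...] = ("26R", "28R")
    symmetry_cancellation: bool = True
    symmetry_breaker_labels: frozenset[str] = frozenset({"NO2"})

    def tables(self):
        rng = np.random.default_rng(self.seed)
        n_g, n_f = self.pattern.n_groups, len(self.library)
        base = {
            s: np.abs(rng.normal(0.0, self.base_scale, size=(n_g, n_f)))
            for s in self.states
        }
        coupling = {
            s: rng.normal(0.0, self.coupling_scale, size=(n_g, n_f, n_g, n_f))
            if self.coupling_scale > 0
            else np.zeros((n_g, n_f, n_g, n_f))
            for s in self.states
        }
        return base, coupling


def synthetic_evaluator(spec: SyntheticLandscapeSpec):
    """Build the deterministic evaluator for a synthetic landscape spec."""
    base, coupling = spec.tables()
    frag_index = {f: i for i, f in enumerate(spec.library)}

    def evaluate(state: str, assignment: cs.Assignment, frequency: float = 0.0) -> float:
        if state not in spec.states:
            raise EvaluatorLookupError(f"{state}({assignment.key_body})", frequency)
        try:
            idx = [frag_index[c] for c in assignment.choices]
        except KeyError as exc:
            raise cs.ChemSpaceError(
                f"fragment {exc.args[0]!r} missing from landscape library"
            ) from None
        if spec.symmetry_cancellation:
            site_map = cs.expand_assignment(assignment)
            if cs.is_formally_centrosymmetric(state, site_map) and not (
                set(assignment.choices) & spec.symmetry_breaker_labels
            ):
                return 0.0
        b = base[state]
        total = sum(b[g, f] for g, f in enumerate(idx))
        c = coupling[state]
        for g in range(len(idx)):
            for h in range(g + 1, len(idx)):
                total += c[g, idx[g], h, idx[h]]
        return abs(float(total))

    return evaluate


# --- file-based external-evaluator contract ---------------------------------

def write_request(job_dir, state: str, assignment: cs.Assignment,
                  frequency: float = 0.0) -> Path:
    """Write a structure request file; returns its path.

    The external responder must place a β tensor in the ``hexanlo-beta-v1``
    JSON dialect at :func:`response_path_for` of the request.
    """
    job_dir = Path(job_dir)
    job_dir.mkdir(parents=True, exist_ok=True)
    structure = cs.SwitchStructure(state, assignment)
    req = {
        "key": structure.key,
        "state": state,
        "site_map": cs.expand_assignment(assignment),
        "frequency_eV": frequency,
    }
    safe = structure.key.replace("(", "_").replace(")", "").replace("/", "-")
    path = job_dir / f"request_{safe}_{frequency:g}.json"
    path.write_text(json.dumps(req, indent=1))
    return path


def response_path_for(request_path) -> Path:
    p = Path(request_path)
    return p.with_name(p.name.replace("request_", "response_").replace(".json", ".beta.json"))


class ExternalEvaluator:
    """Evaluator delegating β tensors to an external program via files.

    For each structure it writes a request file into ``job_dir``, waits for
    the responder to deposit the tensor file, and reduces it to β_HRS with
    the closed-form HRS invariants.  ``responder`` (optional) is a callable
    invoked synchronously with the request path — used by tests and
    single-process drivers; production responders watch the directory.
    Missing or malformed responses raise, and the search error policy decides
    whether that aborts the run.
    """

    def __init__(self, job_dir, responder=None, timeout: float = 60.0,
                 poll_interval: float = 0.1):
        self.job_dir = Path(job_dir)
        self.responder = responder
        self.timeout = timeout
        self.poll_interval = poll_interval

    def __call__(self, state: str, assignment: cs.Assignment,
                 frequency: float = 0.0) -> float:
        request = write_request(self.job_dir, state, assignment, frequency)
        if self.responder is not None:
            self.responder(request)
        response = response_path_for(request)
        deadline = time.monotonic() + self.timeout
        while not response.exists():
            if time.monotonic() >= deadline:
                raise TimeoutError(f"no response file {response} after {self.timeout}s")
            time.sleep(self.poll_interval)
        tensor = nlo_tensor.read_beta_tensor(response)
        return nlo_tensor.beta_hrs(tensor).beta_hrs
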