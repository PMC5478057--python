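"""Capture histories, study design and dataset containers.

The observation alphabet is the standard multistate coding: 0 = not
captured, 1..4 = captured alive in one of four states (1: not-yet-breeding
female at colony N, 2: not-yet-breeding at colony R, 3: experienced breeder
at N, 4: experienced breeder at R).  Females marked as adults are assigned
to the breeder states from the start; females marked as juveniles start in
states 1/2 and move irreversibly to 3/4 at their first observed breeding.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

JUVENILE = "juvenile"
ADULT = "adult"

#: live-state codes, in matrix order: nb-N, nb-R, br-N, br-R
NONBREEDER_CODES = (1, 2)
BREEDER_CODES = (3, 4)

STATE_COLONY = {1: 0, 2: 1, 3: 0, 4: 1}  # colony index (N=0, R=1) per code


class InvalidHistoryError(ValueError):
    """A capture history violates the data model."""


class DesignError(ValueError):
    """A study design is internally inconsistent."""


@dataclass(frozen=True)
class CaptureHistory:
    """One marked female's per-occasion observation codes."""

    individual_id: str
    species: str
    age_at_marking: str  # JUVENILE or ADULT
    observations: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "observations", tuple(int(o) for o in self.observations))
        self._check()

    def _check(self) -> None:
        obs = self.observations
        if self.age_at_marking not in (JUVENILE, ADULT):
            raise InvalidHistoryError(
                f"{self.individual_id}: unknown age at marking {self.age_at_marking!r}"
            )
        if any(o not in (0, 1, 2, 3, 4) for o in obs):
            bad = next(o for o in obs if o not in (0, 1, 2, 3, 4))
            raise InvalidHistoryError(f"{self.individual_id}: unknown state code {bad}")
        if not any(obs):
            raise InvalidHistoryError(f"{self.individual_id}: no capture in history")
        if self.age_at_marking == ADULT and any(o in NONBREEDER_CODES for o in obs):
            raise InvalidHistoryError(
                f"{self.individual_id}: adult-marked female carries a non-breeder code"
            )
        if self.age_at_marking == JUVENILE:
            if obs[self.release_occasion] not in NONBREEDER_CODES:
                raise InvalidHistoryError(
                    f"{self.individual_id}: juvenile-marked female released in a breeder state"
                )
            seen_breeder = False
            for o in obs:
                if o in BREEDER_CODES:
                    seen_breeder = True
                elif o in NONBREEDER_CODES and seen_breeder:
                    raise InvalidHistoryError(
                        f"{self.individual_id}: reversal from breeder to non-breeder state"
                    )

    @property
    def release_occasion(self) -> int:
        """Index of the first (marking) capture."""
        return next(i for i, o in enumerate(self.observations) if o)

    @property
    def release_state(self) -> int:
        return self.observations[self.release_occasion]

    @property
    def n_occasions(self) -> int:
        return len(self.observations)

    def key(self) -> tuple:
        """Identity-free content key (used for round-trip comparisons)."""
        return (self.species, self.age_at_marking, self.observations)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: occasions, colonies, species and covariate calendar.

    ``cockchafer_years`` maps each colony label to the set of years with a
    mass cockchafer flight around that roost; the study-wide indicator used
    by the pulse-resource covariates is the union over colonies.
    ``releases`` (optional) schedules newly marked females per
    (year, colony, species, age-at-marking) and is consumed by the
    simulator.
    """

    occasion_labels: tuple[int, ...]
    skipped_occasions: frozenset[int] = frozenset()
    colonies: tuple[str, str] = ("N", "R")
    species: tuple[str, ...] = ("A",)
    cockchafer_years: dict = field(default_factory=dict)
    releases: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "occasion_labels", tuple(self.occasion_labels))
        object.__setattr__(self, "skipped_occasions", frozenset(self.skipped_occasions))
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "colonies", tuple(self.colonies))
        if len(self.occasion_labels) < 2:
            raise DesignError("a design needs at least two occasions")
        if len(set(self.occasion_labels)) != len(self.occasion_labels):
            raise DesignError("duplicate occasion labels")
        if self.occasion_labels[0] in self.skipped_occasions:
            raise DesignError("the first occasion cannot be skipped")
        if not self.skipped_occasions <= set(self.occasion_labels):
            raise DesignError("skipped occasions must be occasions")
        for col, yrs in self.cockchafer_years.items():
            if col not in self.colonies:
                raise DesignError(f"unknown colony {col!r} in cockchafer calendar")
            if not set(yrs) <= set(self.occasion_labels):
                raise DesignError("cockchafer years must be occasion years")

    # -- indexing helpers ------------------------------------------------
    @property
    def n_occasions(self) -> int:
        return len(self.occasion_labels)

    @property
    def n_intervals(self) -> int:
        return self.n_occasions - 1

    def occasion_index(self, year) -> int:
        return self.occasion_labels.index(year)

    def is_skipped(self, occ: int) -> bool:
        return self.occasion_labels[occ] in self.skipped_occasions

    @property
    def recapture_occasions(self) -> tuple[int, ...]:
        """Occasion indices (>=1) at which capture took place."""
        return tuple(
            t for t in range(1, self.n_occasions) if not self.is_skipped(t)
        )

    @property
    def combined_cockchafer_years(self) -> frozenset:
        out: set = set()
        for yrs in self.cockchafer_years.values():
            out |= set(yrs)
        return frozenset(out)

    def cockchafer_flag(self, year) -> int:
        return int(year in self.combined_cockchafer_years)

    def interval_cockchafer_flag(self, interval: int) -> int:
        """Pulse-resource status of interval t -> t+1 (the ending year)."""
        return self.cockchafer_flag(self.occasion_labels[interval + 1])

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "years": list(self.occasion_labels),
            "skipped": sorted(self.skipped_occasions),
            "colonies": list(self.colonies),
            "species": list(self.species),
            "cockchafer_years": {c: sorted(y) for c, y in self.cockchafer_years.items()},
            "releases": [
                {"year": y, "colony": c, "species": s, "age": a, "count": n}
                for (y, c, s, a), n in sorted(self.releases.items(), key=str)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        releases = {
            (r["year"], r["colony"], r["species"], r["age"]): int(r["count"])
            for r in d.get("releases", [])
        }
        return cls(
            occasion_labels=tuple(d["years"]),
            skipped_occasions=frozenset(d.get("skipped", [])),
            colonies=tuple(d.get("colonies", ("N", "R"))),
            species=tuple(d.get("species", ("A",))),
            cockchafer_years={c: frozenset(y) for c, y in d.get("cockchafer_years", {}).items()},
            releases=releases,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Dataset:
    design: StudyDesign
    histories: tuple[CaptureHistory, ...]

    def __post_init__(self):
        object.__setattr__(self, "histories", tuple(self.histories))
        for h in self.histories:
            validate_history(h, self.design)

    def __len__(self) -> int:
        return len(self.histories)

    def subset(self, species=None) -> "Dataset":
        hs = [h for h in self.histories if species is None or h.species == species]
        return Dataset(self.design, tuple(hs))

    def equivalent_to(self, other: "Dataset") -> bool:
        """Content equality ignoring individual ids and row order."""
        return (
            self.design.occasion_labels == other.design.occasion_labels
            and Counter(h.key() for h in self.histories)
            == Counter(h.key() for h in other.histories)
        )


def validate_history(h: CaptureHistory, design: StudyDesign) -> None:
    if h.n_occasions != design.n_occasions:
        raise InvalidHistoryError(
            f"{h.individual_id}: history length {h.n_occasions} != "
            f"{design.n_occasions} occasions"
        )
    if h.species not in design.species:
        raise InvalidHistoryError(f"{h.individual_id}: unknown species {h.species!r}")
    for t in range(design.n_occasions):
        if design.is_skipped(t) and h.observations[t] != 0:
            raise InvalidHistoryError(
                f"{h.individual_id}: capture recorded at skipped occasion "
                f"{design.occasion_labels[t]}"
            )


# ---------------------------------------------------------------------------
# CSV dialect: header 'id,species,age_at_marking,<year>,...'; codes 0-4.
# ---------------------------------------------------------------------------

def read_histories(path, design: StudyDesign, errors: str = "raise"):
    """Read capture histories from CSV.

    With ``errors='raise'`` returns a :class:`Dataset`; the first malformed
    row aborts with its line number.  With ``errors='collect'`` returns
    ``(Dataset, problems)`` where ``problems`` is a list of
    ``(line_number, message)`` for every rejected row.
    """
    df = pd.read_csv(path, dtype=str)
    expected = ["id", "species", "age_at_marking"] + [str(y) for y in design.occasion_labels]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise InvalidHistoryError(f"missing columns: {missing}")
    year_cols = [str(y) for y in design.occasion_labels]

    ok, problems = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            obs = tuple(int(row[c]) for c in year_cols)
            h = CaptureHistory(
                individual_id=str(row["id"]),
                species=str(row["species"]),
                age_at_marking=str(row["age_at_marking"]),
                observations=obs,
            )
            validate_history(h, design)
        except (ValueError, TypeError) as exc:
            if errors == "raise":
                raise InvalidHistoryError(f"line {line}: {exc}") from exc
            problems.append((line, str(exc)))
            continue
        ok.append(h)
    ds = Dataset(design, tuple(ok))
    if errors == "collect":
        return ds, problems
    return ds


def write_histories(dataset: Dataset, path) -> None:
    cols = ["id", "species", "age_at_marking"] + [str(y) for y in dataset.design.occasion_labels]
    rows = [
        [h.individual_id, h.species, h.age_at_marking, *h.observations]
        for h in dataset.histories
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def summarize(dataset: Dataset) -> pd.DataFrame:
    """Marked totals per species, known-age subset and per-colony totals.

    Colony of a female is the colony of her first capture.  Known-age
    females are exactly the juvenile-marked ones.
    """
    design = dataset.design
    idx = list(design.species)
    out = pd.DataFrame(
        0,
        index=pd.Index(idx, name="species"),
        columns=["marked", "known_age"] + [f"colony_{c}" for c in design.colonies],
    )
    for h in dataset.histories:
        out.loc[h.species, "marked"] += 1
        if h.age_at_marking == JUVENILE:
            out.loc[h.species, "known_age"] += 1
        col = design.colonies[STATE_COLONY[h.release_state]]
        out.loc[h.species, f"colony_{col}"] += 1
    return out


# ---------------------------------------------------------------------------
# MARK-style .inp interchange: '<digits> <freq per species group> ;'
# ---------------------------------------------------------------------------

def export_inp(dataset: Dataset, path) -> None:
    """Write histories in the .inp interchange format.

    One record per line: the state-digit string, one frequency column per
    species group, a terminating ';'.  Juvenile- vs adult-marking is
    recoverable from the state of first capture, individual ids are not
    carried by the format.
    """
    design = dataset.design
    counts = Counter(h.key() for h in dataset.histories)
    lines = []
    for (species, _age, obs), n in sorted(counts.items(), key=str):
        digits = "".join(str(o) for o in obs)
        freqs = ["0"] * len(design.species)
        freqs[design.species.index(species)] = str(n)
        lines.append(f"{digits} {' '.join(freqs)};")
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_inp(path, design: StudyDesign) -> Dataset:
    """Read an .inp file back into a Dataset (ids regenerated)."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    histories = []
    k = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("/*"):
            continue
        if not line.endswith(";"):
            raise InvalidHistoryError(f"record does not end in ';': {line!r}")
        parts = line[:-1].split()
        digits, freqs = parts[0], parts[1:]
        if len(freqs) != len(design.species):
            raise InvalidHistoryError(f"expected {len(design.species)} group columns: {line!r}")
        obs = tuple(int(d) for d in digits)
        first = next(o for o in obs if o)
        age = JUVENILE if first in NONBREEDER_CODES else ADULT
        for species, f in zip(design.species, freqs):
            for _ in range(int(f)):
                histories.append(
                    CaptureHistory(f"ind{k:05d}", species, age, obs)
                )
                k += 1
    return Dataset(design, tuple(histories))
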