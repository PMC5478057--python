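"""Model structures and their coding into free parameters.

A candidate model is declared with the compact field notation, e.g.::

    phi(juv: year; ad: spec) psi(juv: .; ad: spec) p(Col*year+rep+spec) alpha(a3+spec)

Each parameter family (survival phi, movement psi, recapture p,
first-breeding alpha) gets a linear model on the logit scale.  Factors are
combined additively (``+``) or interactively (``*``); ``.`` denotes
constancy.  Coding is corner-point (treatment contrasts): an intercept plus
dummies dropping each factor's first level, with interaction terms expanded
patsy-style (``A*B`` = A + B + A:B), so a full interaction has exactly one
free parameter per factor-level combination.

Structural constants are handled outside the linear predictor: recapture is
fixed at 0 at occasions without capture, the probability of starting to
breed at attained age 4 is fixed at 1, and callers may pin whole families
(e.g. ``p`` at 1, or the first-year breeding probability at 0) through
``ModelSpec.fixed``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .data_model import StudyDesign

FAMILIES = ("phi", "psi", "alpha", "p")

_FACTOR_ALIASES = {
    ".": "constant",
    "constant": "constant",
    "year": "year",
    "time": "year",
    "t": "year",
    "spec": "species",
    "species": "species",
    "col": "colony",
    "colony": "colony",
    "rep": "rep_status",
    "status": "rep_status",
    "a2": "age2",
    "a3": "age3",
    "cockchafer": "cockchafer_time",
    "cockchafer(time)": "cockchafer_time",
    "cockchafer(coh)": "cockchafer_cohort",
    "cockchafer(cohort)": "cockchafer_cohort",
}

#: factors each family understands
_ALLOWED = {
    "phi": {"constant", "year", "species", "colony", "age2", "cockchafer_time"},
    "psi": {"constant", "species", "age2"},
    "alpha": {
        "constant",
        "age2",
        "age3",
        "species",
        "colony",
        "cockchafer_time",
        "cockchafer_cohort",
    },
    "p": {"constant", "year", "species", "colony", "rep_status"},
}


class SpecError(ValueError):
    """A model specification cannot be coded against the design."""


# ---------------------------------------------------------------------------
# link functions
# ---------------------------------------------------------------------------

def link(p):
    """Logit link; defined on the open interval (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("link requires 0 < p < 1")
    return logit(p)


def invlink(x):
    """Inverse logit; maps the real line onto (0, 1)."""
    return expit(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# formula parsing
# ---------------------------------------------------------------------------

def _normalize_factor(tok: str) -> str:
    key = tok.strip().lower()
    if key not in _FACTOR_ALIASES:
        raise SpecError(f"unknown factor {tok!r}")
    return _FACTOR_ALIASES[key]


def parse_formula(text: str) -> list[list[str]]:
    """Parse '+/*' notation into expanded product terms.

    ``A*B`` expands to ``[A], [B], [A,B]``; ``.`` yields no terms
    (intercept only).  Returns a list of product terms (each a list of
    factor names), duplicates removed, order preserved.
    """
    terms: list[list[str]] = []
    for chunk in text.split("+"):
        factors = [_normalize_factor(t) for t in chunk.split("*") if t.strip()]
        factors = [f for f in factors if f != "constant"]
        if not factors:
            continue
        # patsy-style expansion of the interaction into all non-empty subsets
        for r in range(1, len(factors) + 1):
            for sub in itertools.combinations(factors, r):
                term = list(sub)
                if term not in terms:
                    terms.append(term)
    return terms


@dataclass(frozen=True)
class EffectTerm:
    """One product term of a family's linear predictor."""

    factors: tuple[str, ...]

    @property
    def interactive(self) -> bool:
        return len(self.factors) > 1


@dataclass(frozen=True)
class ModelSpec:
    """Effect structure for all four parameter families.

    ``survival`` and ``movement`` are either a single formula string (may
    use the ``a2`` age factor) or a mapping ``{'juv': ..., 'ad': ...}`` with
    separate formulas per age class.  ``fixed`` pins whole parameter slices
    to constants; recognised keys: ``phi_juv``, ``phi_ad``, ``alpha1``,
    ``alpha2``, ``alpha3``, ``p``, ``natal``, ``breeding``.
    """

    survival: object = "."
    movement: object = "."
    recapture: str = "."
    first_breeding: str = "."
    fixed: dict = field(default_factory=dict)
    name: str = ""

    _FIXABLE = ("phi_juv", "phi_ad", "alpha1", "alpha2", "alpha3", "p", "natal", "breeding")

    def __post_init__(self):
        for k, v in self.fixed.items():
            if k not in self._FIXABLE:
                raise SpecError(f"unknown fixed slice {k!r}")
            if not 0.0 <= float(v) <= 1.0:
                raise SpecError(f"fixed value for {k} outside [0, 1]")

    def per_class(self, which: str) -> dict:
        """Normalise survival/movement to {'juv': terms, 'ad': terms}."""
        raw = self.survival if which == "phi" else self.movement
        if isinstance(raw, dict):
            sub = {k.strip().lower(): v for k, v in raw.items()}
            if set(sub) != {"juv", "ad"}:
                raise SpecError(f"{which} needs exactly 'juv' and 'ad' sub-models")
            return {k: parse_formula(v) for k, v in sub.items()}
        # single formula: the a2 factor separates the classes; every other
        # factor applies within each class
        terms = parse_formula(str(raw))
        residual = [t for t in terms if "age2" not in t]
        has_a2 = any("age2" in t for t in terms)
        interacts = any("age2" in t and len(t) > 1 for t in terms)
        if interacts or not has_a2:
            # 'a2*spec' (or a classless formula): same structure in each class,
            # coded independently per class
            per = [[f for f in t if f != "age2"] for t in terms]
            per = [t for t in per if t]
            dedup = []
            for t in per:
                if t not in dedup:
                    dedup.append(t)
            return {"juv": dedup, "ad": dedup}
        # additive a2: shared effects across classes handled by the joint
        # coding path (age2 kept as an explicit factor)
        return {"joint": terms}

    def validate(self, design: StudyDesign, strict: bool = False) -> None:
        build_parameter_index(self, design)  # raises on coding errors
        if strict:
            terms = parse_formula(self.recapture)
            if ["colony", "year"] not in terms and ["year", "colony"] not in terms:
                raise SpecError(
                    "study-grade recapture models must keep the colony*year interaction"
                )

    def notation(self) -> str:
        if self.name:
            return self.name

        def fam(raw):
            if isinstance(raw, dict):
                return f"juv: {raw['juv']}; ad: {raw['ad']}"
            return str(raw)

        return (
            f"phi({fam(self.survival)}) psi({fam(self.movement)}) "
            f"p({self.recapture}) alpha({self.first_breeding})"
        )


_NOTATION_RE = re.compile(r"(phi|psi|p|alpha)\s*\(([^()]*(?:\([^()]*\)[^()]*)*)\)")


def parse_model(text: str, fixed: dict | None = None) -> ModelSpec:
    """Parse the full field notation into a :class:`ModelSpec`."""
    found = dict((m.group(1), m.group(2).strip()) for m in _NOTATION_RE.finditer(text))
    unknown = set(found) - {"phi", "psi", "p", "alpha"}
    if unknown:
        raise SpecError(f"unknown families {unknown}")

    def split_classes(body: str):
        if ";" in body or re.search(r"\b(juv|ad)\s*:", body):
            out = {}
            for part in body.split(";"):
                m = re.match(r"\s*(juv|ad)\s*:\s*(.*)", part)
                if not m:
                    raise SpecError(f"cannot parse age-class sub-model {part!r}")
                out[m.group(1)] = m.group(2).strip() or "."
            if set(out) != {"juv", "ad"}:
                raise SpecError("need both 'juv' and 'ad' sub-models")
            return out
        return body or "."

    return ModelSpec(
        survival=split_classes(found.get("phi", ".")),
        movement=split_classes(found.get("psi", ".")),
        recapture=found.get("p", ".") or ".",
        first_breeding=found.get("alpha", ".") or ".",
        fixed=dict(fixed or {}),
        name=text.strip(),
    )


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _treatment_columns(values: dict, terms: list[list[str]], levels: dict, prefix: str):
    """Corner-point model matrix over cells described by ``values``.

    ``values[f]`` holds each cell's level of factor ``f``; ``levels[f]`` the
    ordered levels.  Returns (X, column names); the intercept is always
    included.
    """
    n = len(next(iter(values.values()))) if values else 1
    cols = [np.ones(n)]
    names = [f"{prefix}:(Int)"]
    for term in terms:
        per_factor = []
        for f in term:
            if f not in values:
                raise SpecError(f"factor {f!r} not applicable here")
            present = set(values[f])
            lv = [l for l in levels[f] if l in present]
            if len(lv) < 2:
                per_factor.append([])  # single-level factor contributes nothing
                continue
            per_factor.append(
                [((values[f] == l).astype(float), f"{f}[{l}]") for l in lv[1:]]
            )
        if any(len(p) == 0 for p in per_factor):
            continue
        for combo in itertools.product(*per_factor):
            col = np.ones(n)
            for vec, _ in combo:
                col = col * vec
            cols.append(col)
            names.append(prefix + ":" + ":".join(lbl for _, lbl in combo))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SpecError(f"rank-deficient coding for {prefix} (redundant terms)")
    return X, names


@dataclass
class FamilyCoding:
    """Coding of one parameter family's cells.

    ``shape`` is the cell grid; free cells get ``invlink(X @ beta)``, fixed
    cells keep ``fixed_values``.
    """

    name: str
    shape: tuple[int, ...]
    X: np.ndarray          # (n_free_cells, k)
    free_cells: np.ndarray  # flat indices of free cells
    fixed_values: np.ndarray  # flat array, nan on free cells
    param_names: list[str]
    offset: int = 0

    @property
    def n_free(self) -> int:
        return self.X.shape[1] if self.free_cells.size else 0

    def resolve(self, beta_f: np.ndarray) -> np.ndarray:
        theta = self.fixed_values.copy()
        if self.free_cells.size:
            theta[self.free_cells] = invlink(self.X @ beta_f)
        return theta.reshape(self.shape)

    def resolve_se(self, beta_f: np.ndarray, cov_f: np.ndarray) -> np.ndarray:
        """Delta-method SEs on the probability scale (0 on fixed cells)."""
        se = np.zeros(int(np.prod(self.shape)))
        if self.free_cells.size and cov_f.size:
            eta = self.X @ beta_f
            var_eta = np.einsum("ij,jk,ik->i", self.X, cov_f, self.X)
            var_eta = np.clip(var_eta, 0.0, np.inf)
            theta = invlink(eta)
            cell_se = np.sqrt(var_eta) * theta * (1.0 - theta)
            cell_se[np.abs(eta) > 10.0] = np.nan  # boundary: SE unreliable
            se[self.free_cells] = cell_se
        return se.reshape(self.shape)


@dataclass
class ParameterIndex:
    """Resolved coding of a ModelSpec against a StudyDesign."""

    spec: ModelSpec
    design: StudyDesign
    families: dict
    n_free: int
    param_names: list[str]

    def split(self, beta: np.ndarray) -> dict:
        out = {}
        for name, fam in self.families.items():
            out[name] = np.asarray(beta[fam.offset : fam.offset + fam.n_free], dtype=float)
        return out

    def resolve(self, beta: np.ndarray):
        from .transitions import RateSet  # local import to avoid a cycle

        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free parameters, got {beta.shape}")
        parts = self.split(beta)
        grids = {name: fam.resolve(parts[name]) for name, fam in self.families.items()}
        return _grids_to_rateset(grids, self.design, RateSet)

    def resolve_se(self, beta: np.ndarray, cov: np.ndarray):
        from .transitions import RateSet

        parts = self.split(beta)
        grids = {}
        for name, fam in self.families.items():
            cov_f = cov[fam.offset : fam.offset + fam.n_free,
                        fam.offset : fam.offset + fam.n_free]
            grids[name] = fam.resolve_se(parts[name], cov_f)
        return _grids_to_rateset(grids, self.design, RateSet, se_mode=True)


def _grids_to_rateset(grids, design, RateSet, se_mode=False):
    S = len(design.species)
    T = design.n_occasions
    I = T - 1

    phi = grids["phi"]              # (2, S, 2, I): ageclass, species, colony, interval
    psi = grids["psi"]              # (2, 2, S): kind, direction, species
    alpha_g = grids["alpha"]        # (3, S, 2, 2, 2): age, species, colony, tflag, cflag
    p_g = grids["p"]                # (2, T-1, 2, S): colony, occ-1, status, species

    alpha = np.zeros((4, S, 2, I, 2))
    for t in range(I):
        tf = design.interval_cockchafer_flag(t)
        alpha[:3, :, :, t, :] = alpha_g[:, :, :, tf, :]
    alpha[3] = 0.0 if se_mode else 1.0  # forced breeding at attained age 4

    p = np.zeros((S, 2, 2, T))
    for occ in range(1, T):
        p[:, :, :, occ] = p_g[:, occ - 1, :, :].transpose(2, 0, 1)

    return RateSet(
        phi_juv=phi[0],
        phi_ad=phi[1],
        alpha=alpha,
        natal=psi[0].T.copy(),      # (S, 2) directions [NR, RN]
        breeding=psi[1].T.copy(),
        p=p,
        validate=not se_mode,
    )


# ---------------------------------------------------------------------------
# family builders
# ---------------------------------------------------------------------------

def _grid_values(axes: dict) -> dict:
    """Flattened per-cell level arrays for a named cell grid."""
    names = list(axes)
    mesh = np.meshgrid(*[np.arange(len(axes[a])) for a in names], indexing="ij")
    return {
        a: np.array([axes[a][i] for i in m.ravel()], dtype=object)
        for a, m in zip(names, mesh)
    }


def _year_levels(design: StudyDesign, intervals: bool) -> list:
    if intervals:
        return [design.occasion_labels[t + 1] for t in range(design.n_intervals)]
    return [design.occasion_labels[t] for t in design.recapture_occasions]


def _build_phi(spec: ModelSpec, design: StudyDesign):
    S, I = len(design.species), design.n_intervals
    shape = (2, S, 2, I)
    n_cells = int(np.prod(shape))
    year_of_interval = [design.occasion_labels[t + 1] for t in range(I)]
    coc = [str(design.interval_cockchafer_flag(t)) for t in range(I)]
    levels = {
        "age2": ["juv", "ad"],
        "species": list(design.species),
        "colony": list(design.colonies),
        "year": sorted(set(year_of_interval)),
        "cockchafer_time": ["0", "1"],
    }
    base = _grid_values(
        {
            "age2": ["juv", "ad"],
            "species": list(design.species),
            "colony": list(design.colonies),
            "interval": list(range(I)),
        }
    )
    values = {
        "age2": base["age2"],
        "species": base["species"],
        "colony": base["colony"],
        "year": np.array([year_of_interval[i] for i in base["interval"]], dtype=object),
        "cockchafer_time": np.array([coc[i] for i in base["interval"]], dtype=object),
    }

    fixed = np.full(n_cells, np.nan)
    cls = spec.per_class("phi")
    flat_class = np.array([0 if a == "juv" else 1 for a in values["age2"]])
    fix_juv = "phi_juv" in spec.fixed
    fix_ad = "phi_ad" in spec.fixed
    if fix_juv:
        fixed[flat_class == 0] = float(spec.fixed["phi_juv"])
    if fix_ad:
        fixed[flat_class == 1] = float(spec.fixed["phi_ad"])
    free_mask = np.isnan(fixed)

    blocks, names = [], []
    if "joint" in cls:
        idx = np.where(free_mask)[0]
        sub = {f: v[idx] for f, v in values.items()}
        if idx.size:
            X, nm = _treatment_columns(sub, cls["joint"], levels, "phi")
            blocks.append((idx, X))
            names += nm
    else:
        for ci, cname in enumerate(("juv", "ad")):
            idx = np.where(free_mask & (flat_class == ci))[0]
            if not idx.size:
                continue
            sub = {f: v[idx] for f, v in values.items() if f != "age2"}
            X, nm = _treatment_columns(sub, cls[cname], levels, f"phi_{cname}")
            blocks.append((idx, X))
            names += nm
    return _assemble("phi", shape, blocks, names, fixed)


def _build_psi(spec: ModelSpec, design: StudyDesign):
    S = len(design.species)
    shape = (2, 2, S)  # kind (natal, breeding), direction (NR, RN), species
    n_cells = int(np.prod(shape))
    fixed = np.full(n_cells, np.nan)
    cls = spec.per_class("psi")
    if "joint" in cls:  # additive a2 across movement classes: code per class anyway
        cls = {"juv": [t for t in cls["joint"] if "age2" not in t],
               "ad": [t for t in cls["joint"] if "age2" not in t]}

    flat = np.arange(n_cells).reshape(shape)
    fix_key = {"juv": "natal", "ad": "breeding"}
    blocks, names = [], []
    for ki, kname in enumerate(("juv", "ad")):
        idx = flat[ki].ravel()
        if fix_key[kname] in spec.fixed:
            fixed[idx] = float(spec.fixed[fix_key[kname]])
            continue
        terms = cls[kname]
        extra = {f for t in terms for f in t} - {"species"}
        if extra:
            raise SpecError(f"movement supports only species effects, got {extra}")
        # baseline is always direction-specific: cell means over direction
        # (x species when the species factor is present)
        if any("species" in t for t in terms):
            # cell means over direction x species (rows ordered likewise)
            X = np.eye(2 * S)
            nm = [
                f"psi_{fix_key[kname]}:dir[{dn}]:species[{sp}]"
                for dn in ("NR", "RN")
                for sp in design.species
            ]
        else:
            X = np.zeros((2 * S, 2))
            rows = [(d, s) for d in range(2) for s in range(S)]
            for r, (d, s) in enumerate(rows):
                X[r, d] = 1.0
            nm = [f"psi_{fix_key[kname]}:dir[{dn}]" for dn in ("NR", "RN")]
        blocks.append((idx, X))
        names += nm
    return _assemble("psi", shape, blocks, names, fixed)


def _build_alpha(spec: ModelSpec, design: StudyDesign):
    S = len(design.species)
    shape = (3, S, 2, 2, 2)  # age (1..3), species, colony, tflag, cflag
    n_cells = int(np.prod(shape))
    terms = parse_formula(spec.first_breeding)
    for t in terms:
        bad = set(t) - _ALLOWED["alpha"]
        if bad:
            raise SpecError(f"alpha does not support factors {bad}")

    base = _grid_values(
        {
            "age": ["1", "2", "3"],
            "species": list(design.species),
            "colony": list(design.colonies),
            "tflag": ["0", "1"],
            "cflag": ["0", "1"],
        }
    )
    values = {
        "age3": base["age"],
        "age2": np.where(base["age"] == "1", "1", "2+"),
        "species": base["species"],
        "colony": base["colony"],
        "cockchafer_time": base["tflag"],
        "cockchafer_cohort": base["cflag"],
    }
    levels = {
        "age3": ["1", "2", "3"],
        "age2": ["1", "2+"],
        "species": list(design.species),
        "colony": list(design.colonies),
        "cockchafer_time": ["0", "1"],
        "cockchafer_cohort": ["0", "1"],
    }
    fixed = np.full(n_cells, np.nan)
    ages = base["age"]
    for a in ("1", "2", "3"):
        key = f"alpha{a}"
        if key in spec.fixed:
            fixed[ages == a] = float(spec.fixed[key])
    free_mask = np.isnan(fixed)
    idx = np.where(free_mask)[0]
    blocks, names = [], []
    if idx.size:
        sub = {f: v[idx] for f, v in values.items()}
        X, names = _treatment_columns(sub, terms, levels, "alpha")
        blocks.append((idx, X))
    return _assemble("alpha", shape, blocks, names, fixed)


def _build_p(spec: ModelSpec, design: StudyDesign):
    S, T = len(design.species), design.n_occasions
    shape = (2, T - 1, 2, S)  # colony, occasion-1, status (nb, br), species
    n_cells = int(np.prod(shape))
    terms = parse_formula(spec.recapture)
    for t in terms:
        bad = set(t) - _ALLOWED["p"]
        if bad:
            raise SpecError(f"recapture does not support factors {bad}")

    base = _grid_values(
        {
            "colony": list(design.colonies),
            "occ": list(range(1, T)),
            "status": ["nb", "br"],
            "species": list(design.species),
        }
    )
    occ_year = {t: design.occasion_labels[t] for t in range(1, T)}
    values = {
        "colony": base["colony"],
        "year": np.array([occ_year[o] for o in base["occ"]], dtype=object),
        "rep_status": base["status"],
        "species": base["species"],
    }
    levels = {
        "colony": list(design.colonies),
        "year": [occ_year[t] for t in design.recapture_occasions],
        "rep_status": ["nb", "br"],
        "species": list(design.species),
    }
    fixed = np.full(n_cells, np.nan)
    skipped = np.array([design.is_skipped(o) for o in base["occ"]])
    fixed[skipped] = 0.0
    if "p" in spec.fixed:
        fixed[~skipped] = float(spec.fixed["p"])
    free_mask = np.isnan(fixed)
    idx = np.where(free_mask)[0]
    blocks, names = [], []
    if idx.size:
        sub = {f: v[idx] for f, v in values.items()}
        X, names = _treatment_columns(sub, terms, levels, "p")
        blocks.append((idx, X))
    return _assemble("p", shape, blocks, names, fixed)


def _assemble(name, shape, blocks, names, fixed):
    """Stack per-class blocks into one FamilyCoding (block-diagonal X)."""
    if not blocks:
        return FamilyCoding(
            name=name,
            shape=shape,
            X=np.zeros((0, 0)),
            free_cells=np.array([], dtype=int),
            fixed_values=fixed,
            param_names=[],
        )
    total_k = sum(X.shape[1] for _, X in blocks)
    free_cells = np.concatenate([idx for idx, _ in blocks])
    Xfull = np.zeros((free_cells.size, total_k))
    r = c = 0
    for idx, X in blocks:
        Xfull[r : r + X.shape[0], c : c + X.shape[1]] = X
        r += X.shape[0]
        c += X.shape[1]
    order = np.argsort(free_cells, kind="stable")
    return FamilyCoding(
        name=name,
        shape=shape,
        X=Xfull[order],
        free_cells=free_cells[order],
        fixed_values=fixed,
        param_names=names,
    )


def build_parameter_index(spec: ModelSpec, design: StudyDesign) -> ParameterIndex:
    """Code a ModelSpec into free parameters against a design."""
    fams = {
        "phi": _build_phi(spec, design),
        "psi": _build_psi(spec, design),
        "alpha": _build_alpha(spec, design),
        "p": _build_p(spec, design),
    }
    offset = 0
    names: list[str] = []
    for fam in fams.values():
        fam.offset = offset
        offset += fam.n_free
        names += fam.param_names
    return ParameterIndex(
        spec=spec, design=design, families=fams, n_free=offset, param_names=names
    )
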