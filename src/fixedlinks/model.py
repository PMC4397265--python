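"""Model specifications for fixed-links confirmatory factor analysis.

A fixed-links model is a CFA for repeated-measures designs in which the
factor loadings are *fixed* to a predetermined course across task
conditions while the latent variance is freely estimated.  Because the
loadings are fixed, several latent variables can be defined over the
same set of manifest variables, as long as their loading courses are not
proportional to one another.  A "constant" latent (all loadings equal)
absorbs processes unaffected by the experimental manipulation; a
"dynamic" latent (loadings varying with condition) absorbs the
manipulated process.

This module defines :class:`LoadingCourse`, :class:`ModelSpec` and
builders for the model family analysed in the accompanying study: a
congeneric one-factor model (Model 1), four two-latent fixed-links
models with linear, quadratic, logarithmic and inverted-u dynamic
courses (Models 2-5), and two structural models regressing a reasoning
factor on the working-memory latents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "FREE",
    "Parameter",
    "fixed",
    "LoadingCourse",
    "ModelSpec",
    "ValidationReport",
    "make_course",
    "build_paper_model",
    "validate_spec",
    "COURSE_NAMES",
    "PAPER_MODELS",
]


@dataclass(frozen=True)
class Parameter:
    """A model parameter: either free (estimated) or fixed at ``value``."""

    free: bool
    value: float | None = None

    def __post_init__(self):
        if not self.free and self.value is None:
            raise ValueError("fixed parameter needs a value")
        if self.value is not None and not math.isfinite(self.value):
            raise ValueError("parameter value must be finite")

    def __repr__(self):
        return "FREE" if self.free else f"fixed({self.value:g})"


FREE = Parameter(free=True)


def fixed(value: float) -> Parameter:
    return Parameter(free=False, value=float(value))


COURSE_NAMES = ("constant", "linear", "quadratic", "logarithmic", "inverted_u")

#: x-values generating the inverted-u course via f(x) = (-x^2 + 100)/100
INVERTED_U_X = (-8.0, -4.5, -1.0, 2.5, 6.0)


@dataclass(frozen=True)
class LoadingCourse:
    """A named, ordered vector of fixed loading weights across conditions.

    The course encodes a hypothesis about how a latent process scales
    with task demand: ``constant`` (all ones) for demand-independent
    processes, monotone increasing courses (linear, quadratic,
    logarithmic) for processes growing with load, and ``inverted_u``
    for processes whose expression collapses once capacity is exceeded.
    """

    name: str
    values: tuple[float, ...]

    def __post_init__(self):
        v = self.values
        if len(v) < 2:
            raise ValueError("a loading course needs at least 2 conditions")
        if not all(math.isfinite(x) for x in v):
            raise ValueError("loading values must be finite")
        if self.name == "constant":
            if any(x != v[0] for x in v):
                raise ValueError("constant course must have equal values")
        elif self.name in ("linear", "quadratic", "logarithmic"):
            if not all(b > a for a, b in zip(v, v[1:])):
                raise ValueError(f"{self.name} course must be strictly increasing")
        elif self.name == "inverted_u":
            peak = v.index(max(v))
            if peak in (0, len(v) - 1):
                raise ValueError("inverted_u course must have an interior maximum")
            rise, fall = v[: peak + 1], v[peak:]
            if not all(b > a for a, b in zip(rise, rise[1:])):
                raise ValueError("inverted_u course must rise to its maximum")
            if not all(b < a for a, b in zip(fall, fall[1:])):
                raise ValueError("inverted_u course must fall after its maximum")
        elif self.name != "custom":
            raise ValueError(f"unknown course name {self.name!r}")

    def __len__(self):
        return len(self.values)

    def is_proportional_to(self, other: "LoadingCourse", tol: float = 1e-12) -> bool:
        """True if the two courses are scalar multiples of each other."""
        if len(self) != len(other):
            return False
        a, b = self.values, other.values
        # find a reference pair with both entries nonzero
        for ai, bi in zip(a, b):
            if abs(ai) > tol and abs(bi) > tol:
                ratio = ai / bi
                return all(abs(x - ratio * y) <= tol * max(1.0, abs(x)) for x, y in zip(a, b))
        return all(abs(x) <= tol and abs(y) <= tol for x, y in zip(a, b))


def make_course(name, n_conditions=5, params=None):
    """Build a named loading course over ``n_conditions`` conditions.

    The named courses reproduce, at two-decimal precision, the series
    used in the study design (set sizes 2-6 dots, five conditions):

    ==============  =============================================
    constant        1, 1, 1, 1, 1
    linear          .1, .2, .3, .4, .5
    quadratic       .01, .04, .09, .16, .25  (squares of linear)
    logarithmic     log10(k+1), k = 1..n  -> .30, .48, .60, .70, .78
    inverted_u      f(x) = (-x^2 + 100)/100 at x = -8, -4.5, -1,
                    2.5, 6  -> .36, .80, .99, .94, .64
    ==============  =============================================

    Named courses are rounded to 2 decimals (the precision at which
    fixed loadings enter the models); ``custom`` courses are returned
    unrounded.

    Parameters
    ----------
    name : str
        One of ``constant``, ``linear``, ``quadratic``, ``logarithmic``,
        ``inverted_u``, ``custom``.
    n_conditions : int
        Number of repeated-measures conditions (>= 2).
    params : dict, optional
        For ``inverted_u``: ``{"x": sequence}`` of x-values in (-10, 10),
        default the five design values. For ``custom``:
        ``{"values": sequence}``.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2")
    params = dict(params or {})
    k = range(1, n_conditions + 1)
    if name == "constant":
        vals = [1.0] * n_conditions
    elif name == "linear":
        vals = [i / 10 for i in k]
    elif name == "quadratic":
        vals = [(i / 10) ** 2 for i in k]
    elif name == "logarithmic":
        vals = [math.log10(i + 1) for i in k]
    elif name == "inverted_u":
        x = tuple(params.get("x", INVERTED_U_X[:n_conditions]))
        if len(x) != n_conditions:
            raise ValueError("inverted_u needs one x-value per condition")
        if any(not -10 < xi < 10 for xi in x):
            raise ValueError("inverted_u x-values must lie in (-10, 10)")
        vals = [(-(xi**2) + 100) / 100 for xi in x]
    elif name == "custom":
        vals = [float(v) for v in params["values"]]
        if len(vals) != n_conditions:
            raise ValueError("custom values length must equal n_conditions")
        return LoadingCourse("custom", tuple(vals))
    else:
        raise ValueError(f"unknown course label {name!r}")
    return LoadingCourse(name, tuple(round(v, 2) for v in vals))


@dataclass
class ModelSpec:
    """Declarative specification of a structural equation model.

    The model follows the all-latent formulation: manifest variables y
    load on latents eta via Lambda, latents regress on each other via B
    (acyclic), Psi holds latent (co)variances / disturbance variances,
    Theta holds manifest residual variances.  The implied covariance is

        Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta

    Every entry is a :class:`Parameter` (``FREE`` or ``fixed(v)``);
    absent loadings / covariances / paths are implicitly fixed at 0.
    """

    manifest_names: list[str]
    latent_names: list[str]
    loadings: dict[tuple[str, str], Parameter] = field(default_factory=dict)
    latent_variances: dict[str, Parameter] = field(default_factory=dict)
    latent_covariances: dict[tuple[str, str], Parameter] = field(default_factory=dict)
    structural_paths: dict[tuple[str, str], Parameter] = field(default_factory=dict)
    residual_variances: dict[str, Parameter] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        for m in self.manifest_names:
            self.residual_variances.setdefault(m, FREE)
        for l in self.latent_names:
            self.latent_variances.setdefault(l, FREE)

    # -- bookkeeping ---------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.manifest_names)

    @property
    def m(self) -> int:
        return len(self.latent_names)

    def free_parameter_names(self) -> list[str]:
        """Names of free parameters in canonical packing order.

        Order: loadings (``L=~y``), latent variances (``L~~L``), latent
        covariances, structural paths (``L1~L2``), residual variances
        (``y~~y``).  lavaan-style naming.
        """
        out = []
        for (y, l), par in self.loadings.items():
            if par.free:
                out.append(f"{l}=~{y}")
        for l, par in self.latent_variances.items():
            if par.free:
                out.append(f"{l}~~{l}")
        for (a, b), par in self.latent_covariances.items():
            if par.free:
                out.append(f"{a}~~{b}")
        for (tgt, src), par in self.structural_paths.items():
            if par.free:
                out.append(f"{tgt}~{src}")
        for y, par in self.residual_variances.items():
            if par.free:
                out.append(f"{y}~~{y}")
        return out

    @property
    def n_free(self) -> int:
        return len(self.free_parameter_names())

    @property
    def df(self) -> int:
        """Model degrees of freedom: p(p+1)/2 minus free parameters."""
        return self.p * (self.p + 1) // 2 - self.n_free

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def enc(par):
            return "free" if par.free else {"fixed": par.value}

        return {
            "name": self.name,
            "manifests": list(self.manifest_names),
            "latents": list(self.latent_names),
            "loadings": {f"{l}=~{y}": enc(p) for (y, l), p in self.loadings.items()},
            "latent_variances": {l: enc(p) for l, p in self.latent_variances.items()},
            "latent_covariances": {f"{a}~~{b}": enc(p) for (a, b), p in self.latent_covariances.items()},
            "structural_paths": {f"{t}~{s}": enc(p) for (t, s), p in self.structural_paths.items()},
            "residual_variances": {y: enc(p) for y, p in self.residual_variances.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        def dec(v):
            if v == "free":
                return FREE
            return fixed(v["fixed"])

        loadings = {}
        for key, v in d.get("loadings", {}).items():
            l, y = key.split("=~")
            loadings[(y, l)] = dec(v)
        latcov = {}
        for key, v in d.get("latent_covariances", {}).items():
            a, b = key.split("~~")
            latcov[(a, b)] = dec(v)
        paths = {}
        for key, v in d.get("structural_paths", {}).items():
            t, s = key.split("~")
            paths[(t, s)] = dec(v)
        return cls(
            manifest_names=list(d["manifests"]),
            latent_names=list(d["latents"]),
            loadings=loadings,
            latent_variances={l: dec(v) for l, v in d.get("latent_variances", {}).items()},
            latent_covariances=latcov,
            structural_paths=paths,
            residual_variances={y: dec(v) for y, v in d.get("residual_variances", {}).items()},
            name=d.get("name", ""),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.from_dict(json.loads(text))


# ----------------------------------------------------------------------
# Builders for the study's models
# ----------------------------------------------------------------------

WMC_NAMES = ["Cond1", "Cond2", "Cond3", "Cond4", "Cond5"]
REASONING_NAMES = ["Figural", "Numerical", "Verbal"]

PAPER_MODELS = (1, 2, 3, 4, 5, "structural_cfa", "structural_fixedlinks")

_DYNAMIC_COURSE = {2: "linear", 3: "quadratic", 4: "logarithmic", 5: "inverted_u"}


def _congeneric_wmc() -> ModelSpec:
    """One WMC factor, free loadings, latent variance fixed to 1."""
    return ModelSpec(
        manifest_names=list(WMC_NAMES),
        latent_names=["WMC"],
        loadings={(y, "WMC"): FREE for y in WMC_NAMES},
        latent_variances={"WMC": fixed(1.0)},
        name="Model 1 (congeneric)",
    )


def _fixed_links_wmc(course_name: str, model_no: int) -> ModelSpec:
    """Constant + dynamic latent over the five WMC conditions.

    Both loading courses are fixed; both latent variances are free; the
    two latents are uncorrelated (their covariance is fixed to 0).
    """
    const = make_course("constant", 5)
    dyn = make_course(course_name, 5)
    loadings = {}
    for i, y in enumerate(WMC_NAMES):
        loadings[(y, "Constant")] = fixed(const.values[i])
        loadings[(y, "Dynamic")] = fixed(dyn.values[i])
    return ModelSpec(
        manifest_names=list(WMC_NAMES),
        latent_names=["Constant", "Dynamic"],
        loadings=loadings,
        latent_variances={"Constant": FREE, "Dynamic": FREE},
        latent_covariances={("Constant", "Dynamic"): fixed(0.0)},
        name=f"Model {model_no} (constant + {course_name})",
    )


def _reasoning_measurement(spec_kwargs: dict) -> None:
    """Add the reasoning factor (3 composites, first loading fixed to 1)."""
    spec_kwargs["manifest_names"] = list(REASONING_NAMES) + spec_kwargs["manifest_names"]
    spec_kwargs["latent_names"] = spec_kwargs["latent_names"] + ["Reasoning"]
    loadings = spec_kwargs["loadings"]
    loadings[(REASONING_NAMES[0], "Reasoning")] = fixed(1.0)
    for y in REASONING_NAMES[1:]:
        loadings[(y, "Reasoning")] = FREE
    spec_kwargs["latent_variances"]["Reasoning"] = FREE  # disturbance variance


def build_paper_model(which) -> ModelSpec:
    """Build one of the study's model specifications.

    Parameters
    ----------
    which : int or str
        ``1`` congeneric WMC model; ``2``-``5`` fixed-links models with
        linear / quadratic / logarithmic / inverted-u dynamic course;
        ``"structural_cfa"`` the congeneric WMC factor predicting a
        Reasoning factor; ``"structural_fixedlinks"`` the two Model-5
        latents each predicting Reasoning.
    """
    if which == 1:
        return _congeneric_wmc()
    if which in _DYNAMIC_COURSE:
        return _fixed_links_wmc(_DYNAMIC_COURSE[which], which)
    if which == "structural_cfa":
        base = _congeneric_wmc()
        kw = dict(
            manifest_names=base.manifest_names,
            latent_names=base.latent_names,
            loadings=dict(base.loadings),
            latent_variances=dict(base.latent_variances),
            latent_covariances={},
            structural_paths={("Reasoning", "WMC"): FREE},
            name="structural_cfa",
        )
        _reasoning_measurement(kw)
        return ModelSpec(**kw)
    if which == "structural_fixedlinks":
        base = _fixed_links_wmc("inverted_u", 5)
        kw = dict(
            manifest_names=base.manifest_names,
            latent_names=base.latent_names,
            loadings=dict(base.loadings),
            latent_variances=dict(base.latent_variances),
            latent_covariances=dict(base.latent_covariances),
            structural_paths={
                ("Reasoning", "Constant"): FREE,
                ("Reasoning", "Dynamic"): FREE,
            },
            name="structural_fixedlinks",
        )
        _reasoning_measurement(kw)
        return ModelSpec(**kw)
    raise ValueError(f"unknown model identifier {which!r}")


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------


@dataclass
class ValidationReport:
    ok: bool
    messages: list[str]

    def __bool__(self):
        return self.ok


def _structural_is_acyclic(spec: ModelSpec) -> bool:
    # Kahn topological sort on latent path graph (edge src -> tgt)
    edges = {(s, t) for (t, s) in spec.structural_paths}
    nodes = set(spec.latent_names)
    indeg = {n: 0 for n in nodes}
    for _, t in edges:
        indeg[t] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for s, t in edges:
            if s == n:
                indeg[t] -= 1
                if indeg[t] == 0:
                    queue.append(t)
    return seen == len(nodes)


def validate_spec(spec: ModelSpec) -> ValidationReport:
    """Check identification and coherence of a model specification.

    Verifies: every latent is scaled (fixed variance or at least one
    nonzero fixed loading); structural paths are acyclic; degrees of
    freedom are non-negative; no two latents over the same manifests
    carry proportional fixed loading courses (which would make them
    inseparable); all fixed values finite.
    """
    msgs = []
    for l in spec.latent_names:
        var = spec.latent_variances.get(l, FREE)
        has_endogenous = any(t == l for (t, _s) in spec.structural_paths)
        fixed_loading = any(
            lat == l and not par.free and par.value != 0
            for (_y, lat), par in spec.loadings.items()
        )
        if var.free and not fixed_loading and not has_endogenous:
            # endogenous latents are scaled through their indicators too
            msgs.append(f"latent {l!r} is not identified: free variance and no nonzero fixed loading")
        if var.free and has_endogenous and not fixed_loading:
            msgs.append(f"endogenous latent {l!r} needs a fixed loading to set its scale")
    if not _structural_is_acyclic(spec):
        msgs.append("structural paths contain a cycle")
    if spec.df < 0:
        msgs.append(f"negative degrees of freedom ({spec.df}): too many free parameters")
    # proportional fixed courses over the same manifest set
    fixed_courses = {}
    for l in spec.latent_names:
        entries = {y: par for (y, lat), par in spec.loadings.items() if lat == l}
        if entries and all(not p.free for p in entries.values()):
            key = tuple(sorted(entries))
            fixed_courses.setdefault(key, []).append(
                (l, LoadingCourse("custom", tuple(entries[y].value for y in sorted(entries))))
            )
    for key, group in fixed_courses.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                (la, ca), (lb, cb) = group[i], group[j]
                if ca.is_proportional_to(cb):
                    msgs.append(
                        f"latents {la!r} and {lb!r} have proportional fixed loading courses: not separable"
                    )
    unknown = [y for y, _ in spec.loadings if y not in spec.manifest_names]
    if unknown:
        msgs.append(f"loadings refer to unknown manifests: {unknown}")
    return ValidationReport(ok=not msgs, messages=msgs)
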