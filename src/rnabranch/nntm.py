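"""NNTM multiloop parameters and their reduction to tree-energy coefficients.

Under the Nearest Neighbor Thermodynamic Model, seven aggregate constants
(all kcal/mol) determine the free energy of the branching-only structures
studied here: the multiloop penalty ``a``, the per-single-stranded-nucleotide
multiloop penalty ``b``, the per-branching-helix penalty ``c``, the helix
energy ``h``, the hairpin energy ``f``, the interior-loop energy ``i`` and
the dangling-end contribution ``g``.

For a plane tree t with down-degree counts d_j, root degree r and n edges,
the total free energy

    d0*f + d1*i + sum_{j>=2} d_j*(a + 4b(j+1) + c(j+1) + g(j+1)) + n*h + g*r

collapses, via sum(d_j) = n and sum(j*d_j) = n - r, to the linear form

    alpha*d0 + beta*d1 + gamma*r + delta*n

with alpha = f - a - 4b - c - g, beta = i - a - 8b - 2c - 2g,
gamma = -4b - c, delta = a + 8b + 2c + h + 2g.  Since n is fixed during
sampling, delta*n is a constant and is dropped; the sampled distribution
also sets gamma = 0, disregarding the (small) exterior-loop term.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields

from .trees import PlaneTree, TwoMotzkinPath, degree_summary

__all__ = [
    "NNTMParameterSet",
    "EnergyCoefficients",
    "derive_coefficients",
    "builtin_parameter_set",
    "BUILTIN_PARAMETERS",
    "tree_energy",
    "full_structure_energy",
    "path_energy",
]


@dataclass(frozen=True)
class NNTMParameterSet:
    """The seven aggregate NNTM inputs, kcal/mol."""

    a: float  # multiloop penalty
    b: float  # per single-stranded nucleotide in a multiloop
    c: float  # per helix branching from a multiloop
    h: float  # helix energy
    f: float  # hairpin energy
    i: float  # interior-loop energy
    g: float  # dangling-end contribution
    label: str = ""

    def __post_init__(self) -> None:
        for fld in ("a", "b", "c", "h", "f", "i", "g"):
            value = getattr(self, fld)
            if not math.isfinite(value):
                raise ValueError(f"NNTM parameter {fld!r} must be finite, got {value}")

    @classmethod
    def from_mapping(cls, data: dict, label: str = "") -> "NNTMParameterSet":
        required = {"a", "b", "c", "h", "f", "i", "g"}
        missing = required - data.keys()
        if missing:
            raise ValueError(f"missing NNTM parameters: {sorted(missing)}")
        return cls(label=label or str(data.get("label", "")),
                   **{k: float(data[k]) for k in sorted(required)})

    @classmethod
    def from_text(cls, text: str, label: str = "") -> "NNTMParameterSet":
        """Parse a JSON object or key=value lines with keys a,b,c,h,f,i,g."""
        text = text.strip()
        if text.startswith("{"):
            return cls.from_mapping(json.loads(text), label=label)
        data: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = float(value)
        return cls.from_mapping(data, label=label)


@dataclass(frozen=True)
class EnergyCoefficients:
    """Reduced coefficients of the linear tree-energy function, kcal/mol.

    ``alpha`` multiplies the leaf count d0, ``beta`` the interior-node count
    d1, ``gamma`` the root degree r, and ``delta`` the edge count n.  Values
    are carried at full precision; one-decimal rounding is display only.
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        for fld in fields(self):
            value = getattr(self, fld.name)
            if not math.isfinite(value):
                raise ValueError(f"coefficient {fld.name!r} must be finite, got {value}")


def derive_coefficients(params: NNTMParameterSet) -> EnergyCoefficients:
    """Reduce the seven NNTM inputs to (alpha, beta, gamma, delta)."""
    a, b, c, h, f, i, g = (params.a, params.b, params.c, params.h,
                           params.f, params.i, params.g)
    return EnergyCoefficients(
        alpha=f - a - 4 * b - c - g,
        beta=i - a - 8 * b - 2 * c - 2 * g,
        gamma=-4 * b - c,
        delta=a + 8 * b + 2 * c + h + 2 * g,
    )


# (Y, Z, Turner revision) -> a, b, c, h, f, i, g for the two combinatorial
# sequences A^4 (Y^5 Z A^4 Y Z^5 A^4)^n whose maximally paired structures
# realize all plane trees.
BUILTIN_PARAMETERS: dict[tuple[str, str, int], NNTMParameterSet] = {
    ("C", "G", 89): NNTMParameterSet(4.6, 0.4, 0.1, -10.9, 3.8, 3.0, -1.6, "CG-Turner89"),
    ("G", "C", 89): NNTMParameterSet(4.6, 0.4, 0.1, -16.5, 3.5, 3.0, -1.9, "GC-Turner89"),
    ("C", "G", 99): NNTMParameterSet(3.4, 0.0, 0.4, -12.9, 4.5, 2.3, -1.6, "CG-Turner99"),
    ("G", "C", 99): NNTMParameterSet(3.4, 0.0, 0.4, -16.9, 4.1, 2.3, -1.9, "GC-Turner99"),
    ("C", "G", 4): NNTMParameterSet(9.3, 0.0, -0.9, -12.9, 4.5, 2.3, -1.1, "CG-Turner04"),
    ("G", "C", 4): NNTMParameterSet(9.3, 0.0, -0.9, -16.9, 4.1, 2.3, -1.5, "GC-Turner04"),
}


def builtin_parameter_set(y: str, z: str, turner: int) -> NNTMParameterSet:
    """Built-in parameter row for sequence pair (Y, Z) and a Turner revision.

    ``turner`` is 89, 99 or 4 (2004; 04 also accepted).
    """
    key = (str(y).upper(), str(z).upper(), int(turner) % 100)
    if key not in BUILTIN_PARAMETERS:
        options = ", ".join(f"({a},{b},{t:02d})" for a, b, t in sorted(BUILTIN_PARAMETERS))
        raise KeyError(
            f"no built-in parameters for (Y={y}, Z={z}, Turner={turner}); "
            f"available: {options}"
        )
    return BUILTIN_PARAMETERS[key]


def tree_energy(
    tree: PlaneTree,
    coeffs: EnergyCoefficients,
    include_root_term: bool = False,
    include_delta_term: bool = False,
) -> float:
    """E(t) = alpha*d0 + beta*d1 [+ gamma*r] [+ delta*n].

    With both flags off this is the sampled energy, which disregards the
    exterior loop (gamma) and the constant per-edge term (delta).
    """
    ds = degree_summary(tree)
    energy = coeffs.alpha * ds.d0 + coeffs.beta * ds.d1
    if include_root_term:
        energy += coeffs.gamma * ds.root_degree
    if include_delta_term:
        energy += coeffs.delta * ds.n
    return energy


def full_structure_energy(
    down_degree_counts,
    root_degree: int,
    n: int,
    params: NNTMParameterSet,
) -> float:
    """Structure energy summed loop-by-loop, before any coefficient reduction.

    ``down_degree_counts`` is the sequence d_0, d_1, ... of non-root node
    counts by number of children.  The two identities sum(d_k) = n and
    sum(k*d_k) = n - root_degree are enforced; they are what makes this sum
    equal to the reduced linear form.
    """
    d = list(down_degree_counts)
    if sum(d) != n:
        raise ValueError(
            f"degree identity sum(d_k) = n violated: sum is {sum(d)}, n is {n}"
        )
    weighted = sum(k * dk for k, dk in enumerate(d))
    if weighted != n - root_degree:
        raise ValueError(
            "degree identity sum(k*d_k) = n - r violated: "
            f"sum is {weighted}, n - r is {n - root_degree}"
        )
    p = params
    d0 = d[0] if d else 0
    d1 = d[1] if len(d) > 1 else 0
    multiloops = sum(
        dj * (p.a + 4 * p.b * (j + 1) + p.c * (j + 1) + p.g * (j + 1))
        for j, dj in enumerate(d)
        if j >= 2
    )
    return d0 * p.f + d1 * p.i + multiloops + n * p.h + p.g * root_degree


def path_energy(path: TwoMotzkinPath | str, coeffs: EnergyCoefficients) -> float:
    """E(x) = alpha*(|x|_U + |x|_H + 1) + beta*|x|_I.

    Under the tree<->path bijection this equals the flags-off tree energy of
    the corresponding tree: |x|_U + |x|_H + 1 = d0 and |x|_I = d1.
    """
    if isinstance(path, str):
        path = TwoMotzkinPath(path)
    return (
        coeffs.alpha * (path.count("U") + path.count("H") + 1)
        + coeffs.beta * path.count("I")
    )
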