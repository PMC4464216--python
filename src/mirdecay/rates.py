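"""Named first-order rate constants (min^-1) for mRNA degradation networks.

The rate vocabulary follows the standard notation of kinetic models of
miRNA-mediated decay:

* ``lambda``  — entry into the alternative (miRNA-independent) pathway
* ``mu``      — direct degradation from the initial, unbound state
* ``nu``      — degradation from the alternative-pathway state
* ``lambda_R`` / ``mu_R``     — recruitment by / degradation via miRISC alone
* ``lambda_RN`` / ``mu_RN``   — recruitment by / degradation via miRISC+NOT1
* ``lambda_RNP`` / ``mu_RNP`` — recruitment by / degradation via miRISC+NOT1+PAN3
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping

KNOWN_SYMBOLS: frozenset[str] = frozenset(
    {
        "lambda",
        "mu",
        "nu",
        "lambda_R",
        "mu_R",
        "lambda_RN",
        "mu_RN",
        "lambda_RNP",
        "mu_RNP",
    }
)


class RateSet(Mapping[str, float]):
    """Immutable map from rate symbol to a nonnegative finite value in min^-1.

    Parameters
    ----------
    rates
        Mapping of rate symbols to values.  Symbols outside the recognized
        vocabulary are rejected unless ``allow_custom=True``.
    allow_custom
        Permit user-defined rate symbols (for custom network topologies).
    """

    def __init__(self, rates: Mapping[str, float], *, allow_custom: bool = False):
        clean: dict[str, float] = {}
        for symbol, value in rates.items():
            if not isinstance(symbol, str):
                raise TypeError(f"rate symbol must be a string, got {symbol!r}")
            if symbol not in KNOWN_SYMBOLS and not allow_custom:
                raise KeyError(
                    f"unknown rate symbol {symbol!r}; pass allow_custom=True "
                    f"to use symbols outside {sorted(KNOWN_SYMBOLS)}"
                )
            v = float(value)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {symbol!r} must be finite and >= 0, got {value!r}")
            clean[symbol] = v
        self._rates = clean

    def __getitem__(self, symbol: str) -> float:
        try:
            return self._rates[symbol]
        except KeyError:
            raise KeyError(f"rate symbol {symbol!r} not present in this RateSet") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._rates)

    def __len__(self) -> int:
        return len(self._rates)

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v:g}" for k, v in self._rates.items())
        return f"RateSet({body})"

    def updated(self, **changes: float) -> "RateSet":
        """Return a copy with some rates replaced."""
        merged = dict(self._rates)
        merged.update(changes)
        return RateSet(merged, allow_custom=True)

    def to_dict(self) -> dict[str, float]:
        return dict(self._rates)


#: Point estimates of the fitted rate constants reported for the five
#: knockdown conditions of the miR-9b / F-Luc-Nerfin experiment in
#: D. melanogaster S2 cells (units min^-1).  These serve as the reference
#: parameter set for synthetic experiments and round-trip tests.
REFERENCE_RATES = RateSet(
    {
        "lambda": 0.0008,
        "mu": 0.0276,
        "nu": 0.0028,
        "lambda_R": 0.0023,
        "mu_R": 0.0052,
        "lambda_RN": 0.046,
        "mu_RN": 0.0461,
        "lambda_RNP": 0.1501,
        "mu_RNP": 0.0493,
    }
)

#: Reported 95% confidence intervals for the reference rates.
REFERENCE_RATE_CIS: dict[str, tuple[float, float]] = {
    "lambda": (0.0002, 0.0013),
    "mu": (0.0229, 0.0324),
    "nu": (0.0018, 0.0038),
    "lambda_R": (0.0, 0.0052),
    "mu_R": (0.0030, 0.0074),
    "lambda_RN": (0.0305, 0.0687),
    "mu_RN": (0.0319, 0.0602),
    "lambda_RNP": (0.0908, 0.2094),
    "mu_RNP": (0.0373, 0.0612),
}
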