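"""Radiomic feature-name grammar: parsing and anatomy tallies.

Feature names follow the four-token grammar

    <modality>_<filter>_<family>_<feature>

with ``_`` separating the tokens and ``-`` allowed only inside the filter
token.  Modalities are the seven MRI sequences (ADC, ASL, DWI, FLAIR, T1,
T1CE, T2); filters are ``original``, the eight 3D wavelet sub-bands
``wavelet-XXX`` (X in {L, H}) and the Laplacian-of-Gaussian channels
``log-sigma-<s>-mm-3D`` with sigma in {0.5, 1.0, 2.0, 3.0} mm; families are
the seven standard radiomic descriptor groups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

MODALITIES = ("ADC", "ASL", "DWI", "FLAIR", "T1", "T1CE", "T2")
FAMILIES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
LOG_SIGMAS = ("0.5", "1.0", "2.0", "3.0")

# alternate spellings of post-contrast T1 seen in the wild
_MODALITY_ALIASES = {
    "T1-CONTRAST": "T1CE",
    "T1-GD": "T1CE",
    "T1 CE": "T1CE",
    "T1-CE": "T1CE",
    "T1CE": "T1CE",
}

_VALID_FILTERS = (
    {"original"}
    | {f"wavelet-{b}" for b in WAVELET_SUBBANDS}
    | {f"log-sigma-{s}-mm-3D" for s in LOG_SIGMAS}
)


class FeatureNameError(ValueError):
    """Raised when a feature name does not match the grammar."""


@dataclass(frozen=True)
class FeatureName:
    """Parsed radiomic feature name.

    ``raw`` is preserved verbatim so that ``serialize`` round-trips exactly;
    the component fields hold the normalized tokens.
    """

    raw: str
    modality: str
    filter: str
    family: str
    feature: str

    def serialize(self) -> str:
        """Return the original string (round-trip identity)."""
        return self.raw

    @property
    def filter_class(self) -> str:
        """One of ``original``, ``wavelet``, ``log``."""
        if self.filter == "original":
            return "original"
        if self.filter.startswith("wavelet-"):
            return "wavelet"
        return "log"

    @property
    def subband(self) -> str | None:
        """Wavelet sub-band (e.g. ``LLH``) or None for non-wavelet filters."""
        if self.filter.startswith("wavelet-"):
            return self.filter.split("-", 1)[1]
        return None

    @property
    def log_sigma(self) -> str | None:
        """LoG sigma in mm (as printed, e.g. ``3.0``) or None."""
        if self.filter.startswith("log-sigma-"):
            return self.filter.split("-")[2]
        return None


def _normalize_modality(token: str) -> str:
    up = token.upper()
    if up in _MODALITY_ALIASES:
        return _MODALITY_ALIASES[up]
    if up in MODALITIES:
        return up
    raise FeatureNameError(f"unknown modality token {token!r}")


def parse_feature_name(raw: str) -> FeatureName:
    """Parse ``<modality>_<filter>_<family>_<feature>`` into components.

    Family matching is case-insensitive; post-contrast T1 spellings
    (``T1-contrast``, ``T1-Gd``, ``T1 CE``, ``T1-ce``) normalize to ``T1CE``.
    The terminal feature descriptor may itself contain underscores only if
    the first three tokens parsed unambiguously, so the split is done from
    the left on exactly three separators.

    Raises
    ------
    FeatureNameError
        naming the offending token when the string does not parse.
    """
    if not isinstance(raw, str) or not raw:
        raise FeatureNameError(f"feature name must be a non-empty string, got {raw!r}")
    parts = raw.split("_", 3)
    if len(parts) != 4:
        raise FeatureNameError(
            f"expected 4 '_'-separated tokens in {raw!r}, got {len(parts)}"
        )
    mod_tok, filt_tok, fam_tok, feat_tok = parts
    modality = _normalize_modality(mod_tok)
    if filt_tok not in _VALID_FILTERS:
        raise FeatureNameError(f"unknown filter token {filt_tok!r} in {raw!r}")
    if filt_tok.startswith("wavelet-") and len(filt_tok.split("-", 1)[1]) != 3:
        raise FeatureNameError(f"wavelet sub-band must have 3 letters: {filt_tok!r}")
    family = fam_tok.lower()
    if family not in FAMILIES:
        raise FeatureNameError(f"unknown family token {fam_tok!r} in {raw!r}")
    if not feat_tok:
        raise FeatureNameError(f"empty feature descriptor in {raw!r}")
    return FeatureName(raw=raw, modality=modality, filter=filt_tok, family=family, feature=feat_tok)


def make_feature_name(modality: str, filt: str, family: str, feature: str) -> str:
    """Compose a grammar-compliant name from components (inverse of parsing)."""
    return f"{modality}_{filt}_{family}_{feature}"


@dataclass
class TallyReport:
    """Feature-anatomy counts by filter class, wavelet sub-band, modality and family.

    ``lowpass_heavy`` counts wavelet features whose sub-band contains at
    least two low-pass (L) components; ``by_sigma`` breaks the LoG count
    down by kernel scale.  Every map's values sum to ``total`` except the
    partial maps (``by_subband`` sums to the wavelet count, ``by_sigma`` to
    the LoG count).
    """

    by_filter: dict[str, int] = field(default_factory=dict)
    by_subband: dict[str, int] = field(default_factory=dict)
    by_sigma: dict[str, int] = field(default_factory=dict)
    by_modality: dict[str, int] = field(default_factory=dict)
    by_family: dict[str, int] = field(default_factory=dict)
    lowpass_heavy: int = 0
    total: int = 0

    def as_dict(self) -> dict:
        return {
            "by_filter": dict(self.by_filter),
            "by_subband": dict(self.by_subband),
            "by_sigma": dict(self.by_sigma),
            "by_modality": dict(self.by_modality),
            "by_family": dict(self.by_family),
            "lowpass_heavy": self.lowpass_heavy,
            "total": self.total,
        }

    def format_table(self) -> str:
        """Two-column plain-text rendering of the tallies."""
        lines = []
        for title, mapping in [
            ("filter", self.by_filter),
            ("sub-band", self.by_subband),
            ("LoG sigma", self.by_sigma),
            ("modality", self.by_modality),
            ("family", self.by_family),
        ]:
            if not mapping:
                continue
            lines.append(f"-- by {title} --")
            for key, count in sorted(mapping.items(), key=lambda kv: (-kv[1], kv[0])):
                pct = 100.0 * count / self.total if self.total else 0.0
                lines.append(f"{key:<24s} {count:>5d}  ({pct:.1f}%)")
        lines.append(f"{'total':<24s} {self.total:>5d}")
        return "\n".join(lines)


def tally_features(names: Iterable[FeatureName | str]) -> TallyReport:
    """Count features by filter class, sub-band, sigma, modality and family.

    Accepts parsed :class:`FeatureName` objects or raw strings (parsed here).
    """
    parsed = [n if isinstance(n, FeatureName) else parse_feature_name(n) for n in names]
    if not parsed:
        raise ValueError("tally_features requires a non-empty list of names")
    by_filter: Counter = Counter(p.filter_class for p in parsed)
    by_subband: Counter = Counter(p.subband for p in parsed if p.subband)
    by_sigma: Counter = Counter(p.log_sigma for p in parsed if p.log_sigma)
    by_modality: Counter = Counter(p.modality for p in parsed)
    by_family: Counter = Counter(p.family for p in parsed)
    lowpass_heavy = sum(1 for p in parsed if p.subband and p.subband.count("L") >= 2)
    return TallyReport(
        by_filter=dict(by_filter),
        by_subband=dict(by_subband),
        by_sigma=dict(by_sigma),
        by_modality=dict(by_modality),
        by_family=dict(by_family),
        lowpass_heavy=lowpass_heavy,
        total=len(parsed),
    )
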