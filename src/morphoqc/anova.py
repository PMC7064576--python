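"""Repeated-measures permutation ANOVA on Procrustes-aligned coordinates.

The study design is a balanced nested hierarchy: two cameras (fixed) crossed
with individuals (random), replicate images nested in camera x individual,
and registration iterations nested in replicate. Sums of squares are summed
over all 3V coordinate columns of the aligned configurations (a Procrustes
ANOVA); in a balanced design the orthogonal decomposition below coincides
with Type III marginal sums of squares.

Two formulas are supported:

* ``dense``  — Camera, Individual, Camera:Individual (replicate-to-replicate
  variation within camera x individual), Camera:Individual:Replicate
  (registration-to-registration variation within replicate), Residuals;
* ``sparse`` — Camera, Individual, Camera:Individual, Residuals (one row per
  replicate; no registration level).

F ratios follow the expected-mean-squares logic of a nested random-effects
hierarchy: each term is tested against the mean square of the term nested
immediately below it (Camera and Individual over Camera:Individual;
Camera:Individual over the next level down; the deepest term over the
residual). Significance comes from restricted permutations that shuffle
only units exchangeable under each term's null hypothesis, or optionally
from residual randomization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationSet
from .procrustes import gpa

DENSE_TERMS = ["Camera", "Individual", "Camera:Individual", "Camera:Individual:Replicate"]
SPARSE_TERMS = ["Camera", "Individual", "Camera:Individual"]

FACTOR_COLUMNS = ["camera", "individual", "replicate", "registration"]


@dataclass
class AnovaTable:
    """Term-wise Df/SS/MS/Rsq/F and permutation p, plus the total row."""

    table: pd.DataFrame
    total_df: int
    total_ss: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        """The table with a Total row appended, Table-style column names."""
        out = self.table.rename(columns={"p_perm": f"Pr(>F)_{self.n_perm}"}).copy()
        total = pd.DataFrame(
            [{"term": "Total", "Df": self.total_df, "SS": self.total_ss}]
        )
        return pd.concat([out, total], ignore_index=True)

    def __getitem__(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def flatten_response(
    cset: ConfigurationSet, aligned: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flatten a balanced set into an n x 3V response and its factor frame.

    Row order is sorted by (individual, camera, replicate, registration);
    columns are vertex-major x, y, z. With ``aligned=False`` a joint
    non-scaled, non-reflected GPA across *all* configurations is run first so
    every row lives in a single common shape space.
    """
    if not cset.balanced:
        raise ValueError(
            "the ANOVA requires a balanced set: every individual must have "
            "every camera x replicate x registration cell"
        )
    keys = sorted(
        cset.entries, key=lambda k: (k.individual, k.camera, k.replicate, k.registration)
    )
    configs = [cset.entries[k] for k in keys]
    if not aligned:
        configs = gpa(configs, allow_scale=False, allow_reflection=False).aligned
    Y = np.stack([c.coords.ravel() for c in configs])
    factors = pd.DataFrame(
        {
            "camera": [k.camera for k in keys],
            "individual": [k.individual for k in keys],
            "replicate": [k.replicate for k in keys],
            "registration": [k.registration for k in keys],
        }
    )
    return Y, factors


def _codes(column: pd.Series) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(column, sort=True)
    return codes.astype(np.int64), len(uniques)


def _level_means(Y: np.ndarray, codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(codes, minlength=n).astype(float)
    if np.any(counts == 0):
        raise ValueError("empty design cell: the design is rank-deficient")
    sums = np.zeros((n, Y.shape[1]))
    np.add.at(sums, codes, Y)
    return sums / counts[:, None], counts


def decompose_ss(
    Y: np.ndarray, factors: pd.DataFrame, formula: str = "dense"
) -> dict[str, tuple[float, int]]:
    """Balanced nested decomposition: term -> (SS, Df), plus Residuals and Total.

    SS are summed over all response columns; the components add up to the
    total SS exactly in a balanced design.
    """
    if formula not in ("dense", "sparse"):
        raise ValueError(f"unknown formula {formula!r}; use 'dense' or 'sparse'")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    cam, n_cam = _codes(factors["camera"])
    ind, n_ind = _codes(factors["individual"])
    rep, n_rep = _codes(factors["replicate"])
    ci = cam * n_ind + ind
    cir = ci * n_rep + rep

    grand = Y.mean(axis=0)
    total_ss = float(((Y - grand) ** 2).sum())

    m_c, cnt_c = _level_means(Y, cam, n_cam)
    m_i, cnt_i = _level_means(Y, ind, n_ind)
    m_ci, cnt_ci = _level_means(Y, ci, n_cam * n_ind)
    for cnt in (cnt_c, cnt_i, cnt_ci):
        if not np.allclose(cnt, cnt[0]):
            raise ValueError("unbalanced design: unequal cell counts")

    ss_cam = float((cnt_c[:, None] * (m_c - grand) ** 2).sum())
    ss_ind = float((cnt_i[:, None] * (m_i - grand) ** 2).sum())
    ci_cam = np.repeat(np.arange(n_cam), n_ind)
    ci_ind = np.tile(np.arange(n_ind), n_cam)
    inter = m_ci - m_c[ci_cam] - m_i[ci_ind] + grand
    ss_ci = float((cnt_ci[:, None] * inter**2).sum())

    out: dict[str, tuple[float, int]] = {
        "Camera": (ss_cam, n_cam - 1),
        "Individual": (ss_ind, n_ind - 1),
        "Camera:Individual": (ss_ci, (n_cam - 1) * (n_ind - 1)),
    }
    if formula == "dense":
        m_cir, cnt_cir = _level_means(Y, cir, n_cam * n_ind * n_rep)
        if not np.allclose(cnt_cir, cnt_cir[0]):
            raise ValueError("unbalanced design: unequal registration counts")
        cir_parent = np.arange(n_cam * n_ind * n_rep) // n_rep
        ss_cir = float((cnt_cir[:, None] * (m_cir - m_ci[cir_parent]) ** 2).sum())
        ss_res = float(((Y - m_cir[cir]) ** 2).sum())
        n_reg = int(cnt_cir[0])
        out["Camera:Individual:Replicate"] = (ss_cir, n_cam * n_ind * (n_rep - 1))
        out["Residuals"] = (ss_res, n_cam * n_ind * n_rep * (n_reg - 1))
    else:
        ss_res = float(((Y - m_ci[ci]) ** 2).sum())
        out["Residuals"] = (ss_res, n - n_cam * n_ind)
    out["Total"] = (total_ss, n - 1)
    return out


def _f_ratios(ss_df: dict[str, tuple[float, int]], formula: str) -> dict[str, float]:
    """F per term: numerator MS over the next-nested term's MS.

    A numerically zero numerator (relative to the total MS scale) gives
    F = 0; a positive numerator over a zero denominator gives F = inf.
    """
    total_ss, total_df = ss_df["Total"]
    tiny = 1e-12 * (total_ss / max(total_df, 1))

    def ms(term: str) -> float:
        ss, df = ss_df[term]
        return ss / df if df > 0 else np.nan

    denom = {
        "Camera": "Camera:Individual",
        "Individual": "Camera:Individual",
    }
    if formula == "dense":
        denom["Camera:Individual"] = "Camera:Individual:Replicate"
        denom["Camera:Individual:Replicate"] = "Residuals"
    else:
        denom["Camera:Individual"] = "Residuals"
    out = {}
    for term, d in denom.items():
        mn, md = ms(term), ms(d)
        if mn <= tiny:
            out[term] = 0.0
        elif md <= tiny:
            out[term] = np.inf
        else:
            out[term] = mn / md
    return out


def permutation_scheme(
    term: str,
    factors: pd.DataFrame,
    seed: "int | np.random.Generator",
    formula: str = "dense",
) -> pd.DataFrame:
    """One restricted shuffle of the factor labels for a term's null.

    Exchangeable units are the blocks at the level immediately below the
    tested term, shuffled within their parent stratum:

    * Camera — camera labels permuted across the camera-level blocks within
      each individual (a per-individual flip for two cameras);
    * Individual — individual labels permuted across the per-individual
      blocks within each camera;
    * Camera:Individual — replicate blocks reassigned to cameras within each
      individual (counts per camera preserved);
    * Camera:Individual:Replicate — rows reassigned to replicates within
      each camera x individual cell (counts per replicate preserved).

    Deterministic under a fixed integer seed.
    """
    terms = DENSE_TERMS if formula == "dense" else SPARSE_TERMS
    if term not in terms:
        raise ValueError(f"term {term!r} is not in the {formula} formula ({terms})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = factors.copy()

    if term == "Camera":
        cameras = sorted(factors["camera"].unique())
        for ind, idx in factors.groupby("individual", sort=True).groups.items():
            perm = rng.permutation(cameras)
            mapping = dict(zip(cameras, perm))
            out.loc[idx, "camera"] = factors.loc[idx, "camera"].map(mapping)
    elif term == "Individual":
        for cam, idx in factors.groupby("camera", sort=True).groups.items():
            inds = sorted(factors.loc[idx, "individual"].unique())
            perm = rng.permutation(inds)
            mapping = dict(zip(inds, perm))
            out.loc[idx, "individual"] = factors.loc[idx, "individual"].map(mapping)
    elif term == "Camera:Individual":
        for ind, idx in factors.groupby("individual", sort=True).groups.items():
            sub = factors.loc[idx]
            blocks = sorted(set(zip(sub["camera"], sub["replicate"])))
            new_cams = rng.permutation([c for c, _ in blocks])
            # relabel replicates 1..R within each new camera to keep nesting valid
            rep_counter: dict[str, int] = {}
            mapping = {}
            for (c, r), nc in zip(blocks, new_cams):
                rep_counter[nc] = rep_counter.get(nc, 0) + 1
                mapping[(c, r)] = (nc, rep_counter[nc])
            pairs = list(zip(sub["camera"], sub["replicate"]))
            out.loc[idx, "camera"] = [mapping[p][0] for p in pairs]
            out.loc[idx, "replicate"] = [mapping[p][1] for p in pairs]
    else:  # Camera:Individual:Replicate
        for (_c, _i), idx in factors.groupby(["camera", "individual"], sort=True).groups.items():
            out.loc[idx, "replicate"] = rng.permutation(factors.loc[idx, "replicate"].to_numpy())
    return out


def _residual_blocks(
    Y: np.ndarray, factors: pd.DataFrame, formula: str, term: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Restricted residual-randomization setup for one term.

    Each term is tested against the mean square of the stratum nested
    immediately below it, so the exchangeable units under that term's null
    are the *summaries at that denominator stratum*, permuted within the
    stratum above the term after removing the nuisance fit:

    * Camera — replicate-group residuals (group mean minus individual mean)
      exchanged within each individual, across cameras;
    * Individual — camera x individual cell residuals (cell mean minus
      camera mean) exchanged within each camera, across individuals;
    * Camera:Individual — replicate-group residuals from the additive
      camera + individual fit, exchanged within each individual;
    * Camera:Individual:Replicate — row residuals from the cell mean,
      exchanged within each camera x individual cell.

    Returns (base, block residual matrix, per-row block codes, per-block
    stratum codes): ``base + block_residual[blocks] == Y`` row-wise, and the
    null is generated by permuting block residuals within each stratum.
    This follows the expected-mean-squares logic of the nested random
    hierarchy while offering far finer permutation resolution than whole
    camera-block flips when individuals are few.
    """
    cam, n_cam = _codes(factors["camera"])
    ind, n_ind = _codes(factors["individual"])
    rep, n_rep = _codes(factors["replicate"])
    ci = cam * n_ind + ind
    grand = Y.mean(axis=0)
    m_c, _ = _level_means(Y, cam, n_cam)
    m_i, _ = _level_means(Y, ind, n_ind)
    m_ci, _ = _level_means(Y, ci, n_cam * n_ind)
    rows = np.arange(len(Y))
    if formula == "dense":
        cir = ci * n_rep + rep
        m_cir, _ = _level_means(Y, cir, n_cam * n_ind * n_rep)
        rep_group_mean, rep_groups = m_cir[cir], cir
    else:  # replicate groups are single rows
        rep_group_mean, rep_groups = Y, rows

    if term == "Camera":
        r = rep_group_mean - m_i[ind]
        blocks, strata = rep_groups, ind
    elif term == "Individual":
        r = m_ci[ci] - m_c[cam]
        blocks, strata = ci, cam
    elif term == "Camera:Individual":
        r = rep_group_mean - (m_c[cam] + m_i[ind] - grand)
        blocks, strata = rep_groups, ind
    elif term == "Camera:Individual:Replicate":
        r = Y - m_ci[ci]
        blocks, strata = rows, ci
    else:
        raise ValueError(f"no residual-randomization scheme for term {term!r}")

    uniq, codes = np.unique(blocks, return_inverse=True)
    first = np.zeros(len(uniq), dtype=np.int64)
    first[codes[::-1]] = rows[::-1]
    return Y - r, r[first], codes, strata[first]


def _permute_blocks(
    base: np.ndarray,
    block_r: np.ndarray,
    codes: np.ndarray,
    block_strata: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reassign block residuals uniformly at random within each stratum."""
    perm = np.arange(len(block_r))
    for s in np.unique(block_strata):
        idx = np.flatnonzero(block_strata == s)
        perm[idx] = idx[rng.permutation(len(idx))]
    return base + block_r[perm][codes]


def nested_anova(
    Y: np.ndarray,
    factors: pd.DataFrame,
    formula: str = "dense",
    n_perm: int = 100,
    seed: int = 0,
    scheme: str = "labels",
    terms: "list[str] | None" = None,
) -> AnovaTable:
    """Permutation Procrustes ANOVA for the balanced nested camera design.

    Parameters
    ----------
    Y : (n, p) response of flattened aligned coordinates.
    factors : frame with columns camera, individual, replicate (registration
        ignored — it defines the residual level implicitly in the dense formula).
    formula : "dense" (registration level present) or "sparse".
    n_perm : number of permutations; p values have resolution 1/(n_perm+1)
        and the observed statistic is included in the null set, so p is
        never exactly 0.
    scheme : "labels" (restricted label permutation within exchangeable
        strata) or "residuals" (residual randomization: permute
        reduced-model residuals, add back, re-test).
    terms : restrict permutation testing to these terms (all by default);
        untested terms get NaN p values but full SS/MS/F rows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("labels", "residuals"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    Y = np.asarray(Y, dtype=float)
    if len(Y) != len(factors):
        raise ValueError("response and factor frame have differing row counts")

    all_terms = DENSE_TERMS if formula == "dense" else SPARSE_TERMS
    if terms is None:
        test_terms = all_terms
    else:
        unknown = [t for t in terms if t not in all_terms]
        if unknown:
            raise ValueError(f"terms {unknown} not in the {formula} formula")
        test_terms = list(terms)
    obs = decompose_ss(Y, factors, formula)
    f_obs = _f_ratios(obs, formula)

    rng = np.random.default_rng(seed)
    exceed = {t: 1 for t in test_terms}  # observed statistic included in the null set
    if scheme == "residuals":
        blocks = {t: _residual_blocks(Y, factors, formula, t) for t in test_terms}
    for _ in range(n_perm):
        for term in test_terms:
            if scheme == "labels":
                permuted = permutation_scheme(term, factors, rng, formula)
                f_star = _f_ratios(decompose_ss(Y, permuted, formula), formula)[term]
            else:
                base, block_r, codes, strata = blocks[term]
                Y_star = _permute_blocks(base, block_r, codes, strata, rng)
                f_star = _f_ratios(decompose_ss(Y_star, factors, formula), formula)[term]
            if f_star >= f_obs[term]:
                exceed[term] += 1
    p_perm = {t: exceed[t] / (n_perm + 1) for t in test_terms}

    total_ss, total_df = obs["Total"]
    rows = []
    for term in all_terms + ["Residuals"]:
        ss, df = obs[term]
        rows.append(
            {
                "term": term,
                "Df": df,
                "SS": ss,
                "MS": ss / df if df > 0 else np.nan,
                "Rsq": ss / total_ss if total_ss > 0 else np.nan,
                "F": f_obs.get(term, np.nan),
                "p_perm": p_perm.get(term, np.nan),
            }
        )
    return AnovaTable(
        table=pd.DataFrame(rows), total_df=int(total_df), total_ss=total_ss, n_perm=n_perm
    )
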