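import numpy as np
import pytest

from memcpm import Atlas, GroundTruthSpec, generate_cohort, synthetic_atlas


@pytest.fixture(scope="session")
def atlas60():
    """60-node synthetic atlas covering all 10 networks."""
    return synthetic_atlas(60)


@pytest.fixture(scope="session")
def toy_atlas():
    """Tiny hand-built atlas: A has 3 nodes, B has 4."""
    return Atlas(labels=np.array(["A"] * 3 + ["B"] * 4, dtype=object))


@pytest.fixture(scope="session")
def null_cohort(atlas60):
    """No planted signal: every edge is baseline + noise."""
    spec = GroundTruthSpec(n_female=60, n_male=60, scans=("FACENAME",), seed=11)
    return generate_cohort(spec, atlas60)


@pytest.fixture(scope="session")
def planted_cohort(atlas60):
    """20 within-DMN edges carry female signal, 20 visual-block edges male."""
    from memcpm.cohort import visual_block_pairs, within_network_pairs

    rng = np.random.default_rng(7)
    f_pairs = within_network_pairs(atlas60, "DMN", 20, rng)
    m_pairs = visual_block_pairs(atlas60, 20, rng)
    spec = GroundTruthSpec(
        n_female=100, n_male=100, scans=("FACENAME",), seed=13,
        planted_edges={"F": [(i, j, 0.5) for i, j in f_pairs],
                       "M": [(i, j, 0.5) for i, j in m_pairs]})
    return generate_cohort(spec, atlas60)


def oracle_partial_selection(X, y, C, alpha):
    """Brute-force residualization oracle for edge selection.

    Residualize each edge and the score on [1, C] by explicit least squares,
    correlate residuals, apply the t-transform p-value with df = n - 2 - c.
    """
    from scipy import stats as sps

    n = len(y)
    D = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    c = D.shape[1] - 1
    beta_y, *_ = np.linalg.lstsq(D, y, rcond=None)
    yr = y - D @ beta_y
    pos, neg, rs, ps = [], [], [], []
    for e in range(X.shape[1]):
        beta_x, *_ = np.linalg.lstsq(D, X[:, e], rcond=None)
        xr = X[:, e] - D @ beta_x
        denom = np.sqrt((xr @ xr) * (yr @ yr))
        r = 0.0 if denom == 0 else float(xr @ yr / denom)
        df = n - 2 - c
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1 - r * r))
            p = float(2 * sps.t.sf(abs(t), df))
        rs.append(r)
        ps.append(p)
        if p < alpha and r > 0:
            pos.append(e)
        elif p < alpha and r < 0:
            neg.append(e)
    return np.array(pos, int), np.array(neg, int), np.array(rs), np.array(ps)


def oracle_bh(p, m=None):
    """Quadratic-time Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    n = p.size
    m = n if m is None else m
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, n)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def oracle_association_ratio(matrix, labels, network):
    """Edge-enumeration oracle for the association ratio."""
    n = matrix.shape[0]
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i] == network, labels[j] == network
            if a and b:
                num += matrix[i, j]
                den += matrix[i, j]
            elif a or b:
                den += matrix[i, j]
    return np.nan if den == 0 else num / den


def oracle_spearman(x, y):
    """Rank (average ties) then Pearson, from the definition."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
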