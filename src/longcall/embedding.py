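"""UMAP embeddings of feature tables and midpoint-centered spectrograms,
and the Hopkins statistic of clustering tendency.

Spectrogram inputs are vectorized with a 50 ms Hann window at 50% overlap
(20 Hz frequency, 25 ms time resolution), dB-scaled, band-limited to
50–1000 Hz to suppress low-frequency noise, and flattened row-major. The
embedding is for visualization and clusterability assessment only;
clustering itself runs on the acoustic features.
"""

from __future__ import annotations

import warnings

import numpy as np

from .features import compute_spectrogram


def vectorize_spectrograms(
    clips,
    sample_rate: float,
    window_s: float = 0.05,
    overlap_frac: float = 0.5,
    band: tuple[float, float] = (50.0, 1000.0),
    db_floor: float = -120.0,
) -> np.ndarray:
    """Flatten equal-duration audio clips into spectrogram vectors.

    All clips must share a duration (e.g., the 0.9 s midpoint clips);
    the result is an (n_clips, n_frames * n_in_band_bins) matrix.
    """
    clips = [np.asarray(c, dtype=float) for c in clips]
    if not clips:
        raise ValueError("no clips supplied")
    lengths = {len(c) for c in clips}
    if len(lengths) != 1:
        raise ValueError(f"clips have mixed durations (lengths {sorted(lengths)})")
    n_fft = int(round(window_s * sample_rate))
    vecs = []
    for clip in clips:
        spec = compute_spectrogram(clip, sample_rate, n_fft=n_fft,
                                   overlap_frac=overlap_frac, db_floor=db_floor)
        sel = (spec.bin_freqs >= band[0]) & (spec.bin_freqs <= band[1])
        vecs.append(spec.magnitudes_db[:, sel].ravel())
    return np.vstack(vecs)


def umap_embed(
    matrix,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> tuple[np.ndarray, dict]:
    """2-D UMAP embedding at (logged) default settings.

    Returns the coordinates and a settings record (seed, n_neighbors,
    min_dist) for the run manifest. The UMAP optimizer itself is an
    external dependency.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 10:
        raise ValueError(
            f"need at least 10 rows for a meaningful embedding (got {X.shape[0]}); "
            "reduce n_neighbors or supply more pulses")
    import umap  # deferred: numba compilation is slow at import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=min(n_neighbors, X.shape[0] - 1),
                            min_dist=min_dist, random_state=seed)
        coords = reducer.fit_transform(X)
    settings = {"seed": seed, "n_neighbors": int(min(n_neighbors, X.shape[0] - 1)),
                "min_dist": min_dist, "n_components": 2}
    return np.asarray(coords, dtype=float), settings


def hopkins_statistic(matrix, m_frac: float = 0.1, seed: int = 0) -> float:
    """Hopkins statistic of clustering tendency.

    Compares nearest-neighbor distances of m = ceil(m_frac * n) sampled
    real points (to the remaining data) against m uniform points drawn in
    the data bounding box (to the data): H = sum(u) / (sum(u) + sum(w)).
    H near 0.5 indicates spatial uniformity, near 1 strong clusterability.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 points (got {n})")
    if not 0.0 < m_frac <= 0.5:
        raise ValueError(f"m_frac must be in (0, 0.5] (got {m_frac})")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(m_frac * n))
    sample_idx = rng.choice(n, size=m, replace=False)
    lo, hi = X.min(axis=0), X.max(axis=0)
    U = rng.uniform(lo, hi, size=(m, X.shape[1]))

    rest = np.delete(X, sample_idx, axis=0)
    from scipy.spatial import cKDTree

    w = cKDTree(rest).query(X[sample_idx], k=1)[0]
    u = cKDTree(X).query(U, k=1)[0]
    denom = u.sum() + w.sum()
    return float(u.sum() / denom) if denom > 0 else 0.5
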