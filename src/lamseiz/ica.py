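"""ICA identification of laminar discharge-generation patterns.

Each detected discharge contributes a 1 s CSD window (channels x time)
centered on its peak; the window stack is decomposed with a fixed-point
(FastICA) unmixing into 8 components after whitening.  Components are then
reduced to *patterns*: retained by explained-variance share, merged when
their mean assigned windows correlate strongly, and kept when they have
enough supporting events occupying a temporally contiguous epoch.  The
onset zone of the emulated seizures yields two such patterns (an initial
and a sustained motif); propagation recordings yield one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA

from .csd import CSDMatrix


@dataclass
class ICAResult:
    components: np.ndarray       # k x channels x window samples
    loadings: np.ndarray         # events x k
    var_share: np.ndarray        # k, descending
    windows: np.ndarray          # events x channels x window samples
    event_times_s: np.ndarray
    n_dropped: int


@dataclass
class Pattern:
    component_ids: list[int]
    event_indices: np.ndarray
    epoch_s: tuple[float, float]          # decile-trimmed interval
    epoch_events: tuple[int, int]         # first/last member event index
    mean_motif: np.ndarray                # channels x window samples
    contiguous: bool
    purity: float


@dataclass
class PatternResult:
    n_patterns: int
    patterns: list[Pattern]
    assignment: np.ndarray                # event -> pattern id, -1 unassigned
    switch_times_s: list[float]
    warnings: list[str] = field(default_factory=list)


def build_event_windows(
    csd: CSDMatrix, event_times_s, win_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-event CSD windows centered on the event peak, each normalized by
    its max |CSD|.  Events whose window does not fit the recording are
    dropped; returns (windows, kept event times, n_dropped)."""
    times = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    half = int(round(win_s / 2.0 * csd.fs_hz))
    n = csd.values.shape[1]
    wins, kept = [], []
    for t in times:
        s = csd.sample_at(t)
        if s - half < 0 or s + half > n:
            continue
        w = csd.values[:, s - half : s + half]
        peak = np.abs(w).max()
        wins.append(w / peak if peak > 0 else w)
        kept.append(t)
    if not wins:
        raise ValueError("no event window fits inside the recording")
    return np.stack(wins), np.asarray(kept), times.size - len(wins)


def decompose(
    windows: np.ndarray, event_times_s, n_components: int = 8, seed: int = 0
) -> ICAResult:
    """Fixed-point ICA of the event x (channels*samples) window matrix.

    Whitening retains ``n_components`` principal dimensions; the component
    count is reduced (with a warning) if the stack has lower rank.
    Components are ordered by explained-variance share, descending.
    """
    n_ev, nch, nw = windows.shape
    X = windows.reshape(n_ev, nch * nw)
    max_rank = min(n_ev - 1, X.shape[1])
    k = min(n_components, max_rank)
    if k < n_components:
        warnings.warn(
            f"component count reduced from {n_components} to {k} (rank limit)",
            RuntimeWarning,
        )
    if k < 1:
        raise ValueError("need at least 2 event windows to decompose")
    # Whitening WITHOUT centering: discharge windows share a dominant mean
    # motif, and removing it would leave that motif with no component to
    # load on.  Uncentered SVD keeps it as a (typically the first)
    # principal direction, so every event loads on a motif-like component.
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    Z = U[:, :k] * np.sqrt(n_ev)                  # uncentered-whitened scores
    ica = FastICA(whiten=False, random_state=int(seed), max_iter=1000, tol=1e-4)
    S = ica.fit_transform(Z)                      # events x k
    W = ica.components_                           # k x k rotation
    # map back to signal space: X ~= S @ M with M = W^-T diag(sv/sqrt(n)) V
    M = (np.linalg.inv(W).T * (sv[:k] / np.sqrt(n_ev))[None, :]) @ Vt[:k]
    total_ms = (X**2).mean(axis=0).sum()          # uncentered second moment
    share = (S**2).mean(axis=0) * (M**2).sum(axis=1) / total_ms
    order = np.argsort(share)[::-1]
    return ICAResult(
        components=M[order].reshape(k, nch, nw),
        loadings=S[:, order],
        var_share=share[order],
        windows=windows,
        event_times_s=np.asarray(event_times_s, dtype=float),
        n_dropped=0,
    )


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1, keepdims=True)
    bn = np.linalg.norm(bc, axis=1, keepdims=True)
    an[an == 0] = 1.0
    bn[bn == 0] = 1.0
    return (ac / an) @ (bc / bn).T


def _merge_groups(templates: np.ndarray, merge_corr: float) -> list[list[int]]:
    """Union-find merge of template rows whose correlation >= merge_corr."""
    n = templates.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cm = _corr_rows(templates, templates)
    for a in range(n):
        for b in range(a + 1, n):
            if cm[a, b] >= merge_corr:
                parent[find(a)] = find(b)
    out: dict[int, list[int]] = {}
    for i in range(n):
        out.setdefault(find(i), []).append(i)
    return list(out.values())


def _separation_time(t_a: np.ndarray, t_b: np.ndarray) -> float:
    """Boundary between an earlier (A) and later (B) event set: midpoint of
    the two events straddling the threshold that minimizes misordered
    assignments."""
    cand = np.sort(np.concatenate([t_a, t_b]))
    best_cost, best_tau = None, None
    for i in range(cand.size - 1):
        tau = 0.5 * (cand[i] + cand[i + 1])
        cost = int((t_a > tau).sum() + (t_b < tau).sum())
        if best_cost is None or cost < best_cost:
            best_cost, best_tau = cost, tau
    return float(best_tau if best_tau is not None else cand[0])


def count_patterns(
    ica: ICAResult,
    retain_var: float = 0.03,
    merge_corr: float = 0.5,
    min_support_frac: float = 0.04,
    min_support_events: int = 15,
    min_purity: float = 0.8,
    motif_halfwidth_ms: float = 150.0,
    min_assign_corr: float = 0.25,
) -> PatternResult:
    """Reduce ICA components to temporally organized discharge patterns.

    Events are assigned to the retained component (explained-variance share
    >= ``retain_var``) whose signal-space motif their window correlates with
    best, over the central +/- ``motif_halfwidth_ms`` of the window — the
    part occupied by the discharge itself rather than by neighbouring
    discharges.  Components whose mean assigned central motifs correlate
    >= ``merge_corr`` are merged (distinct laminar motifs correlate near
    or below zero, while finite-sample templates of one motif stay well
    above 0.5), and all events are re-assigned to the
    merged templates (one refinement pass).  A pattern is a merged group
    holding at least max(``min_support_frac`` x n_events,
    ``min_support_events``) events whose decile-trimmed time interval is
    label-pure (>= ``min_purity`` of the events inside it belong to the
    group).  Groups failing the contiguity test are reported with a warning
    but not counted.
    """
    msgs: list[str] = []
    n_ev, nch, nw = ica.windows.shape
    times = ica.event_times_s
    retained = np.nonzero(ica.var_share >= retain_var)[0]
    if retained.size == 0:
        msgs.append("no component reached the variance-share floor")
        return PatternResult(0, [], -np.ones(n_ev, dtype=int), [], msgs)

    # central-motif crop: the window spans 1 s, so the sample half-width is
    # the ms half-width as a fraction of 1000 ms
    half_w = min(nw // 2, max(1, int(round(nw * motif_halfwidth_ms / 1000.0))))
    c0, c1 = nw // 2 - half_w, nw // 2 + half_w
    Xc = ica.windows[:, :, c0:c1].reshape(n_ev, -1)
    Cc = ica.components[retained][:, :, c0:c1].reshape(retained.size, -1)

    # pass 1: seed templates from events assigned to each retained component
    corr = _corr_rows(Xc, Cc)
    dom = np.argmax(corr, axis=1)
    templates = []
    comp_ids: list[list[int]] = []
    for j, c in enumerate(retained):
        sel = dom == j
        if np.any(sel):
            templates.append(Xc[sel].mean(axis=0))
            comp_ids.append([int(c)])
    templates = np.stack(templates)

    # iterative refinement: merge correlated templates, re-assign events to
    # the merged templates (events matching none stay unassigned, e.g.
    # pure-noise windows or spatially inverted rebound detections), drop
    # under-supported groups, rebuild templates from members — to stability
    support = max(min_support_events, int(np.ceil(min_support_frac * n_ev)))
    gdom = -np.ones(n_ev, dtype=int)
    for _ in range(10):
        merged = _merge_groups(templates, merge_corr)
        comp_ids = [sum((comp_ids[i] for i in g), []) for g in merged]
        templates = np.stack([
            np.stack([templates[i] for i in g]).mean(axis=0) for g in merged
        ])
        gcorr = _corr_rows(Xc, templates)
        new_dom = np.argmax(gcorr, axis=1)
        new_dom[gcorr.max(axis=1) < min_assign_corr] = -1
        sizes = np.bincount(new_dom[new_dom >= 0], minlength=templates.shape[0])
        keep = [g for g in range(templates.shape[0]) if sizes[g] >= support]
        if not keep:
            msgs.append("no merged component group reached the support floor")
            return PatternResult(0, [], -np.ones(n_ev, dtype=int), [], msgs)
        if len(keep) < templates.shape[0]:
            assigned = new_dom >= 0
            new_dom[assigned] = np.asarray(keep)[
                np.argmax(gcorr[np.ix_(assigned, keep)], axis=1)
            ]
            comp_ids = [comp_ids[g] for g in keep]
        templates = np.stack([Xc[new_dom == g].mean(axis=0)
                              for g in sorted(set(new_dom[new_dom >= 0]))])
        relabel = {g: i for i, g in enumerate(sorted(set(new_dom[new_dom >= 0])))}
        new_dom = np.asarray([relabel.get(g, -1) for g in new_dom])
        if np.array_equal(new_dom, gdom):
            gdom = new_dom
            break
        gdom = new_dom

    candidates: list[Pattern] = []
    for g in range(templates.shape[0]):
        members = np.nonzero(gdom == g)[0]
        if members.size < support:
            continue
        t_m = np.sort(times[members])
        # epoch = shortest interval holding 80% of the group's events, so a
        # few stray assignments cannot inflate it
        m80 = max(1, int(np.ceil(0.8 * t_m.size)))
        spans = t_m[m80 - 1 :] - t_m[: t_m.size - m80 + 1]
        i0 = int(np.argmin(spans))
        lo, hi = float(t_m[i0]), float(t_m[i0 + m80 - 1])
        inside = np.nonzero((times >= lo) & (times <= hi) & (gdom >= 0))[0]
        purity = np.isin(inside, members).mean() if inside.size else 0.0
        contiguous = purity >= min_purity
        if not contiguous:
            msgs.append(
                f"component group {comp_ids[g]} is temporally non-contiguous "
                f"(purity {purity:.2f}); not counted as a pattern"
            )
        candidates.append(
            Pattern(
                component_ids=[int(c) for c in comp_ids[g]],
                event_indices=members,
                epoch_s=(float(lo), float(hi)),
                epoch_events=(int(members[0]), int(members[-1])),
                mean_motif=ica.windows[members].mean(axis=0),
                contiguous=contiguous,
                purity=float(purity),
            )
        )

    candidates.sort(key=lambda p: float(np.median(times[p.event_indices])))
    counted = [p for p in candidates if p.contiguous]
    assignment = -np.ones(n_ev, dtype=int)
    for pid, p in enumerate(candidates):
        assignment[p.event_indices] = pid
    switch = [
        _separation_time(times[a.event_indices], times[b.event_indices])
        for a, b in zip(counted[:-1], counted[1:])
    ]
    return PatternResult(len(counted), candidates, assignment, switch, msgs)
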