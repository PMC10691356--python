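"""Compiled (numba) evaluation of the batched log-likelihood core.

Same computation as the vectorized numpy path in
:meth:`oceanmix.model.PosteriorKernel` — cohort forward pass plus the CWT,
GSI, run-size, landings and age likelihood components — written as explicit
loops so numba can compile it.  The two paths are cross-checked against each
other (and against the scalar reference accumulation) in the test suite;
this one exists because Hamiltonian sampling with finite-difference
gradients evaluates the posterior tens of thousands of times per fit.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True, error_model="numpy")
def logp_core(
    # batched parameters
    pi, f, f_by_year, v, m, M0dev, U, tau, phi, p2, p2_land,
    # cohort structure
    r_of_j, c_clip, valid, s_of_t, ai_of_t, M_step, is_fall, Jc, link,
    R_release,
    # CWT rows (sorted by step, with step pointers); nbrow_g is gear per row
    cwt_ptr, cwt_row, cwt_j, cwt_l, cwt_g, cwt_lam, cwt_y, nbrow_g,
    uy_vals, uy_cnt, uy_ptr, nb_const,
    # stratum-catch triplets (sorted by step)
    K_strata, trip_ptr, trip_k, trip_j, trip_l, trip_g, trip_r,
    # GSI rows
    gsi_k, gsi_n, gsi_zero, gsi_pos, gsi_multi, gsi_logx,
    # run-size rows
    run_r, run_c, run_logobs, sigma_run,
    # landings rows
    land_k, land_obs, cv_land,
    # age rows (gathers sorted by step)
    age_ptr, age_row, age_col, age_j, age_counts, age_const,
    # component toggles / options
    use_cwt, use_gsi, use_run, use_land, use_age, eq_seq, mean_floor,
    n_years,
):
    B = pi.shape[0]
    J = r_of_j.shape[0]
    T = s_of_t.shape[0]
    L = pi.shape[3]
    G = tau.shape[1]
    Rs = pi.shape[1]
    C = n_years
    n_cwt = cwt_y.shape[0]
    n_gsi = gsi_k.shape[0]
    n_run = run_r.shape[0]
    n_land = land_k.shape[0]
    n_age = age_counts.shape[0]
    n_age_cols = age_counts.shape[1]
    Jt = J - Jc
    LOG2PI = 1.8378770664093453

    out = np.empty(B)
    N = np.empty(J)
    Cbuf = np.empty((J, L, G))
    Ftmp = np.empty(G)
    exp_rec = np.empty(n_cwt)
    mu = np.empty((K_strata, Rs))
    run_buf = np.empty((Rs, C))
    ageN = np.empty((n_age, n_age_cols))

    for b in range(B):
        # --- entry abundance -------------------------------------------
        for j in range(Jc):
            N[j] = R_release[j] * math.exp(-M0dev[b, j])
        for jt in range(Jt):
            acc = U[b, jt]
            for j in range(Jc):
                if link[jt, j] > 0.0:
                    acc += N[j]
            N[Jc + jt] = acc

        for i in range(n_cwt):
            exp_rec[i] = 0.0
        for k in range(K_strata):
            for r in range(Rs):
                mu[k, r] = 0.0
        for r in range(Rs):
            for c in range(C):
                run_buf[r, c] = 0.0
        for i in range(n_age):
            for a in range(n_age_cols):
                ageN[i, a] = 0.0

        # --- forward pass -----------------------------------------------
        for t in range(T):
            s = s_of_t[t]
            ai = ai_of_t[t]
            M = M_step[t]
            fall = is_fall[t]
            for i in range(age_ptr[t], age_ptr[t + 1]):
                ageN[age_row[i], age_col[i]] = N[age_j[i]]
            for j in range(J):
                r = r_of_j[j]
                c = c_clip[j, t]
                surv = 0.0
                for l in range(L):
                    alloc = N[j] * pi[b, r, s, l]
                    Fl = 0.0
                    for g in range(G):
                        if f_by_year:
                            Fg = v[b, ai, g] * f[b, l, s, c, g]
                        else:
                            Fg = v[b, ai, g] * f[b, l, s, 0, g]
                        Ftmp[g] = Fg
                        Fl += Fg
                    if eq_seq:
                        eF = math.exp(-Fl)
                        harvested = 1.0 - eF
                        for g in range(G):
                            share = Ftmp[g] / Fl if Fl > 0.0 else 0.0
                            Cbuf[j, l, g] = alloc * harvested * share
                        surv += alloc * eF * math.exp(-M)
                    else:
                        Z = Fl + M
                        eZ = math.exp(-Z)
                        ratio = (1.0 - eZ) / Z
                        for g in range(G):
                            Cbuf[j, l, g] = alloc * Ftmp[g] * ratio
                        surv += alloc * eZ
                if fall:
                    mat = surv * m[b, r, ai]
                    if j >= Jc and valid[j, t]:
                        run_buf[r, c] += mat
                    N[j] = surv - mat
                else:
                    N[j] = surv
            for i in range(cwt_ptr[t], cwt_ptr[t + 1]):
                exp_rec[cwt_row[i]] = cwt_lam[i] * Cbuf[cwt_j[i], cwt_l[i], cwt_g[i]]
            for i in range(trip_ptr[t], trip_ptr[t + 1]):
                mu[trip_k[i], trip_r[i]] += Cbuf[trip_j[i], trip_l[i], trip_g[i]]

        ll = 0.0

        # --- CWT negative binomial --------------------------------------
        if use_cwt and n_cwt > 0:
            ll += nb_const
            ltau = np.empty(G)
            for g in range(G):
                tg = tau[b, g]
                ltau[g] = math.log(tg)
                lg_t = math.lgamma(tg)
                for i in range(uy_ptr[g], uy_ptr[g + 1]):
                    ll += uy_cnt[i] * (math.lgamma(tg + uy_vals[i]) - lg_t)
            for i in range(n_cwt):
                mu_i = exp_rec[i]
                if mu_i < mean_floor:
                    mu_i = mean_floor
                g = nbrow_g[i]
                tg = tau[b, g]
                ltm = math.log(tg + mu_i)
                ll += tg * (ltau[g] - ltm) + cwt_y[i] * (math.log(mu_i) - ltm)

        # --- GSI zero-and-one-inflated Dirichlet -------------------------
        if use_gsi and n_gsi > 0:
            K = Rs + 1
            ph = phi[b]
            lg_phi = math.lgamma(ph)
            comp = np.empty(K)
            for i in range(n_gsi):
                k = gsi_k[i]
                muF = 0.0
                for r in range(Rs):
                    muF += mu[k, r]
                if muF < 1e-300:
                    muF = 1e-300
                p2i = p2[b, i]
                # expected composition, floored and renormalized
                csum = 0.0
                rawpos = 0.0
                for r in range(Rs):
                    cr = p2i * mu[k, r] / muF
                    if cr < 1e-10:
                        cr = 1e-10
                    comp[r] = cr
                    csum += cr
                co = 1.0 - p2i
                if co < 1e-10:
                    co = 1e-10
                comp[K - 1] = co
                csum += co
                for kk in range(K):
                    if gsi_pos[i, kk]:
                        rawpos += comp[kk]
                n_i = gsi_n[i]
                multi = gsi_multi[i]
                log_empty = 0.0
                patt = 0.0
                dterm = lg_phi
                for kk in range(K):
                    cn = comp[kk] / csum
                    lt0 = n_i * math.log1p(-min(cn, 1.0 - 1e-12))
                    log_empty += lt0
                    if gsi_zero[i, kk]:
                        patt += lt0
                    else:
                        patt += math.log(-math.expm1(min(lt0, -1e-300)))
                        if multi:
                            conc = ph * comp[kk] / rawpos
                            dterm += (conc - 1.0) * gsi_logx[i, kk] - math.lgamma(conc)
                patt -= math.log(-math.expm1(min(log_empty, -1e-300)))
                ll += patt
                if multi:
                    ll += dterm

        # --- run sizes ----------------------------------------------------
        if use_run and n_run > 0:
            for i in range(n_run):
                rh = run_buf[run_r[i], run_c[i]]
                if rh < mean_floor:
                    rh = mean_floor
                z = (run_logobs[i] - math.log(rh)) / sigma_run
                ll += -0.5 * LOG2PI - math.log(sigma_run) - 0.5 * z * z

        # --- landings -----------------------------------------------------
        if use_land and n_land > 0:
            for i in range(n_land):
                mf = 0.0
                for r in range(Rs):
                    mf += mu[land_k[i], r]
                mt = mf / p2_land[b, i]
                if mt < mean_floor:
                    mt = mean_floor
                sd = cv_land * mt
                z = (land_obs[i] - mt) / sd
                ll += -0.5 * LOG2PI - math.log(sd) - 0.5 * z * z

        # --- age compositions ---------------------------------------------
        if use_age and n_age > 0:
            ll += age_const
            for i in range(n_age):
                tot = 0.0
                for a in range(n_age_cols):
                    tot += ageN[i, a]
                if tot < 1e-300:
                    tot = 1e-300
                for a in range(n_age_cols):
                    cnt = age_counts[i, a]
                    if cnt > 0.0:
                        p3 = ageN[i, a] / tot
                        if p3 < 1e-300:
                            p3 = 1e-300
                        ll += cnt * math.log(p3)

        out[b] = ll
    return out
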