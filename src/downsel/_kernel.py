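"""Compiled stepping kernel.

One jitted routine advances the network through a homogeneous segment
(constant clamp/inhibit masks, noise levels, and plasticity rule).  Noise
draws are made outside the kernel (numpy Generator) so that seeding behaves
identically with and without compilation.  The logic here must mirror
:func:`downsel.core.step_network` and the rule functions in
:mod:`downsel.plasticity`; the test suite asserts spike-for-spike agreement.
"""

import numpy as np
from numba import njit

# absorbs float accumulation error in threshold comparisons (weights are sums
# of decimal increments, so exact grid values like 1.0 + 1.0 vs 2.0 must fire)
EPS = 1e-9

RULE_OFF = 0
RULE_WAKE_POTENTIATION = 1
RULE_SLEEP_DOWNSELECTION = 2
RULE_POTENTIATION_IN_SLEEP = 3
RULE_WAKE_STDP = 4
RULE_SLEEP_DOWNSELECTION_ALT = 5


@njit(cache=True)
def run_segment(
    T,
    n,
    spikes1,
    spikes2,
    noise_counts,
    clamp,
    inhibit,
    group_id,
    n_groups,
    intra_w,
    intra_post,
    intra_by_pre_ptr,
    intra_by_pre_idx,
    phantom_src,
    dom_owner,
    neuron_dom_ptr,
    dom_ff_ptr,
    dom_fb_ptr,
    ff_pre,
    ff_w,
    ff_plastic,
    fb_pre,
    fb_w,
    fb_plastic,
    ff_by_pre_ptr,
    ff_by_pre_idx,
    fb_by_pre_ptr,
    fb_by_pre_idx,
    ff_post,
    fb_post,
    w_max,
    z_th,
    threshold,
    fb_window,
    rule,
    alpha_ff,
    alpha_fb,
    beta_ff,
    beta_fb,
    w_ceil,
    fb_ceil,
    conf_ff,
    conf_fb,
    fb_coin_window,
    sustain_steps,
    run_len,
    counts_out,
    raster_out,
    record_raster,
):
    v_ff = np.zeros(n, dtype=np.float64)
    v_fb1 = np.zeros(n, dtype=np.float64)
    v_fb2 = np.zeros(n, dtype=np.float64)
    v_in = np.zeros(n, dtype=np.float64)
    new = np.zeros(n, dtype=np.uint8)
    gcount = np.zeros(n_groups, dtype=np.int64)

    for t in range(T):
        # ---- voltage-independent and feedback drives (event driven) -------
        for i in range(n):
            v_ff[i] = 0.0
            v_fb1[i] = 0.0
            v_fb2[i] = 0.0
            v_in[i] = 0.0
        for pre in range(n):
            if spikes1[pre]:
                for k in range(intra_by_pre_ptr[pre], intra_by_pre_ptr[pre + 1]):
                    v_in[intra_post[intra_by_pre_idx[k]]] += intra_w
        # feedback: a synapse counts once if its pre fired inside the window
        # (v_fb2 collects synapses whose pre fired only at t-2)
        for pre in range(n):
            if spikes1[pre]:
                for k in range(ff_by_pre_ptr[pre], ff_by_pre_ptr[pre + 1]):
                    s = ff_by_pre_idx[k]
                    v_ff[ff_post[s]] += ff_w[s]
                for k in range(fb_by_pre_ptr[pre], fb_by_pre_ptr[pre + 1]):
                    s = fb_by_pre_idx[k]
                    v_fb1[fb_post[s]] += fb_w[s]
            elif fb_window >= 2 and spikes2[pre]:
                for k in range(fb_by_pre_ptr[pre], fb_by_pre_ptr[pre + 1]):
                    s = fb_by_pre_idx[k]
                    v_fb2[fb_post[s]] += fb_w[s]

        # ---- membrane update, spike rule, overrides -----------------------
        for i in range(n):
            if phantom_src[i] >= 0:
                new[i] = spikes1[phantom_src[i]]
                continue
            v_pre = v_ff[i] + w_max * noise_counts[t, i]
            v = v_pre + v_in[i]
            if v_pre > z_th + EPS:
                v += v_fb1[i] + v_fb2[i]
            a = np.uint8(1) if v > threshold + EPS else np.uint8(0)
            if clamp[i]:
                a = np.uint8(1)
            if inhibit[i]:
                a = np.uint8(0)
            new[i] = a

        # ---- plasticity (spikes at t, presynaptic activity at t-1) --------
        if rule != RULE_OFF:
            for i in range(n):
                if phantom_src[i] >= 0:
                    continue
                fired = new[i] == 1
                if rule == RULE_SLEEP_DOWNSELECTION_ALT:
                    if fired:
                        continue
                elif not fired:
                    continue
                # potentiation demands a strong (sustained) postsynaptic
                # burst: spikes on sustain_steps consecutive steps
                sustained = fired and run_len[i] >= sustain_steps - 1
                for d in range(neuron_dom_ptr[i], neuron_dom_ptr[i + 1]):
                    ff_drv = 0.0
                    for s in range(dom_ff_ptr[d], dom_ff_ptr[d + 1]):
                        if spikes1[ff_pre[s]]:
                            ff_drv += ff_w[s]
                    # feedback activity at t-1 (spike count gates the exact
                    # potentiation coincidence) and weighted drive over the
                    # persistence window (gates protection in sleep)
                    fb_act1 = 0
                    fb_drvw = 0.0
                    for s in range(dom_fb_ptr[d], dom_fb_ptr[d + 1]):
                        if spikes1[fb_pre[s]]:
                            if fb_w[s] > EPS:  # eliminated synapses are gone
                                fb_act1 += 1
                            fb_drvw += fb_w[s]
                        elif fb_coin_window >= 2 and spikes2[fb_pre[s]]:
                            fb_drvw += fb_w[s]
                    ff_on = ff_drv >= conf_ff - EPS
                    coincident = ff_on and fb_act1 > 0
                    protected = ff_on and fb_drvw >= conf_fb - EPS
                    if rule == RULE_WAKE_POTENTIATION or rule == RULE_POTENTIATION_IN_SLEEP:
                        if coincident and sustained:
                            for s in range(dom_ff_ptr[d], dom_ff_ptr[d + 1]):
                                if ff_plastic[s] and spikes1[ff_pre[s]]:
                                    ff_w[s] = min(ff_w[s] + alpha_ff, w_ceil)
                            for s in range(dom_fb_ptr[d], dom_fb_ptr[d + 1]):
                                if fb_plastic[s] and spikes1[fb_pre[s]]:
                                    fb_w[s] = min(fb_w[s] + alpha_fb, fb_ceil)
                    elif rule == RULE_SLEEP_DOWNSELECTION:
                        if not protected:
                            for s in range(dom_ff_ptr[d], dom_ff_ptr[d + 1]):
                                if ff_plastic[s] and spikes1[ff_pre[s]]:
                                    ff_w[s] = max(ff_w[s] - beta_ff, 0.0)
                            for s in range(dom_fb_ptr[d], dom_fb_ptr[d + 1]):
                                if fb_plastic[s] and spikes1[fb_pre[s]]:
                                    fb_w[s] = max(fb_w[s] - beta_fb, 0.0)
                    elif rule == RULE_WAKE_STDP:
                        for s in range(dom_ff_ptr[d], dom_ff_ptr[d + 1]):
                            if ff_plastic[s]:
                                if spikes1[ff_pre[s]]:
                                    if coincident and sustained:
                                        ff_w[s] = min(ff_w[s] + alpha_ff, w_ceil)
                                else:
                                    ff_w[s] = max(ff_w[s] - alpha_ff, 0.0)
                        for s in range(dom_fb_ptr[d], dom_fb_ptr[d + 1]):
                            if fb_plastic[s]:
                                if spikes1[fb_pre[s]]:
                                    if coincident and sustained:
                                        fb_w[s] = min(fb_w[s] + alpha_fb, fb_ceil)
                                else:
                                    fb_w[s] = max(fb_w[s] - alpha_fb, 0.0)
                    elif rule == RULE_SLEEP_DOWNSELECTION_ALT:
                        # pilot variant: the neuron did NOT burst; active
                        # (coincident) domains are depressed instead
                        if protected:
                            for s in range(dom_ff_ptr[d], dom_ff_ptr[d + 1]):
                                if ff_plastic[s] and spikes1[ff_pre[s]]:
                                    ff_w[s] = max(ff_w[s] - beta_ff, 0.0)
                            for s in range(dom_fb_ptr[d], dom_fb_ptr[d + 1]):
                                if fb_plastic[s] and spikes1[fb_pre[s]]:
                                    fb_w[s] = max(fb_w[s] - beta_fb, 0.0)

        # ---- bookkeeping and history shift --------------------------------
        for g in range(n_groups):
            gcount[g] = 0
        for i in range(n):
            gcount[group_id[i]] += new[i]
            if new[i]:
                run_len[i] += 1
            else:
                run_len[i] = 0
            spikes2[i] = spikes1[i]
            spikes1[i] = new[i]
        for g in range(n_groups):
            counts_out[t, g] = gcount[g]
        if record_raster:
            for i in range(n):
                raster_out[t, i] = new[i]
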