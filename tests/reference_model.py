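"""Independent scalar transcription of the model equations.

Written term by term from the rate laws, deliberately sharing no code with
the package, so it can serve as an oracle for the assembled right-hand
side.
"""

import math


def literal_rhs(t, y, kin, bio, proto):
    """[dV_os, dCa, dCaMb, dCaNb] from a literal term-by-term evaluation."""
    v_os, ca, camb, canb = y
    ca = max(ca, 0.0)
    camb = min(max(camb, 0.0), kin.CaM_t)
    canb = min(max(canb, 0.0), kin.CaN_t)

    # --- physical half ---
    V = v_os + bio.V_b
    A = (36.0 * math.pi) ** (1.0 / 3.0) * V ** (2.0 / 3.0)
    V0 = bio.V_total0 * math.exp(-bio.P_0 / bio.epsilon)
    P = bio.epsilon * math.log(V / V0) if V >= V0 else 0.0
    cRT = bio.c_PC * bio.R * bio.T
    osm_i0 = bio.c_n_e0 + bio.P_0 / cRT
    v_os0 = bio.V_total0 - bio.V_b
    osm_i = bio.Gly_i + (osm_i0 - bio.Gly_i) * v_os0 / v_os
    if t < proto.t_off:
        osm_e = bio.c_n_e0
        ca_ex = proto.Ca_ex0
    else:
        decay = math.exp((proto.t_off - t) / proto.t_m)
        osm_e = (bio.c_n_e0 - bio.c_n_e0 / proto.d) * decay + bio.c_n_e0 / proto.d
        ca_ex = (proto.Ca_ex0 - proto.Ca_ex0 / proto.d) * decay + proto.Ca_ex0 / proto.d
    dv_os = -bio.L_p * A * (P + cRT * (osm_e - osm_i))

    # --- biochemical half ---
    p_open = 1.0 - 1.0 / (1.0 + math.exp((P - kin.P_MS) / kin.g_MS))
    j_in = kin.v_IN * ca_ex / (kin.k_IN + ca_ex)
    j_pmr1 = kin.v_Pmr1 * ca / (kin.k_Pmr1 + ca)
    j_vcx1 = (kin.v_Vcx1 * ca / (kin.k_Vcx1 + ca)) / (1.0 + kin.kI_Vcx1 * canb)
    j_pmc1 = kin.v_Pmc1 * ca / (kin.k_Pmc1 + ca)
    j_ms = (p_open * kin.k_MS * (ca_ex - ca)) / (1.0 + kin.kI_MS * camb)
    j_cch1 = (kin.k_Cch1 * (ca_ex - ca)) / (1.0 + kin.kI_Cch1 * canb)
    dca = j_in + j_cch1 + j_ms - j_pmr1 - j_vcx1 - j_pmc1

    dcamb = kin.km_plus * (kin.CaM_t - camb) * ca**3 - kin.km_minus * camb
    dcanb = kin.kn_plus * (kin.CaN_t - canb) * camb - kin.kn_minus * canb
    return [dv_os, dca, dcamb, dcanb]
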