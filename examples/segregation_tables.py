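"""Chi-square goodness-of-fit of F2 phenotype counts to a 3:1 ratio.

A monogenic recessive trait segregates 3:1 in an F2 family; a
significant departure (chi2 above 3.84 at 1 df) indicates distortion,
e.g. partial lethality before scoring.
"""

from bsamap import chisq_segregation

families = {
    "F2 family 1 (embryos)": (49, 19),
    "F2 family 4 (embryos)": (46, 32),
    "selfed heterozygote (seedlings)": (175, 32),
}

for label, (n_wt, n_mut) in families.items():
    res = chisq_segregation(n_wt, n_mut)
    flag = "  <- departs from 3:1 at the 5% level" if res.significant_5pct else ""
    print(f"{label}: {n_wt}:{n_mut}  chi2 {res.chi2:.3f}  p {res.p_value:.3f}{flag}")
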