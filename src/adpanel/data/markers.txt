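# adpanel canonical marker registry, version 1
# 27 biomarkers; order is canonical.
amyloid_pet_centiloid
tau_pet_suvr
abeta42_40_plasma
csf_abeta42_40
csf_ptau_abeta40
csf_ttau_abeta40
csf_pT111_T111
csf_pT153_T153
csf_pT175_T175
csf_pT181_T181
csf_pS199_S199
csf_pS202_S202
csf_pT205_T205
csf_pS208_S208
csf_pT217_T217
csf_pT231_T231
csf_nfl
plasma_nfl
mri_cortical_signature
csf_ng
csf_snap25
csf_vilip1
csf_ykl40
csf_strem2
cdr_sb
mmse
prs
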