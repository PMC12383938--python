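cell_line,alpha,alpha_ci_lo,alpha_ci_hi,beta,beta_ci_lo,beta_ci_hi,alpha_beta_ratio,r_squared,dof
A549,0.4822,0.2930,0.6831,0.0093,-0.0602,0.0886,51.69,0.9235,18
Panc-1,-0.05115,-0.1621,0.0579,0.0660,0.0363,0.1013,-0.7747,0.8629,26
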