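#!/usr/bin/env Rscript
# Independent oracle: fit Value ~ Strain + (1|Block) + (1|Block:Replicate)
# with family Gamma(log) via glmmTMB and print the estimates.
suppressMessages(library(glmmTMB))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
d$Block <- factor(d$block)
d$Replicate <- factor(d$replicate)
d$Strain <- factor(d$strain)
m <- glmmTMB(value ~ Strain + (1 | Block) + (1 | Block:Replicate),
             family = Gamma(link = "log"), data = d)
co <- fixef(m)$cond
vc <- VarCorr(m)$cond
cat("coef", sprintf("%.10f", co), "\n")
cat("loglik", sprintf("%.8f", as.numeric(logLik(m))), "\n")
cat("var_block", sprintf("%.8f", attr(vc$Block, "stddev")^2), "\n")
cat("var_rep", sprintf("%.8f", attr(vc$`Block:Replicate`, "stddev")^2), "\n")
cat("shape", sprintf("%.6f", sigma(m)^-2), "\n")
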