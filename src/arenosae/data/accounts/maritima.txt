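5.0–20.0 cm tall, spreading. Stem pubescent in lower part, scabrous, pubescent with sessile glands in upper part; with 5–8 distinct internodes, the uppermost internode (0.5–)1.0–3.0 cm long and obviously longer than the next upper internode. Basal leaves oblanceolate 10.0–30.0× 1.0–3.0 mm, pubescent. Cauline leaves oblanceolate 10.0–30.0 × 1.0–3.0 mm, pubescent. Calyx 13.0–15.0 mm long, campanulate at anthesis and clavate in fruit, pubescent; teeth unequal; shorter ones 2.0–3.0 mm, lanceolate, acuminate; longer ones 2.0–4.0 mm, lanceolate, acuminate marginal hairs long (longer than 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 6.0–7.5 mm long, ciliate; limbs 5.0–6.5 mm long, bifid, upper-surface white, lobes oblong, petal limbs cleft to middle or more, lower-surface white; coronal scales 0.9–1.5 mm long, ovate, apex laciniate or dentate. Anthophore 5.0–6.0 mm long, tomentose or puberulent. Anthers exserted; filaments 6.0–9.0 mm long, sparsely pubescent . Styles slightly exserted. First pedicel 1.0–2.0 cm early flower, 1.0–2.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 6.0–8.0 mm long, oblong, fragile, opaque. Seeds 0.7–0.9 mm wide, 0.4–0.7 mm high, testa smooth.
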