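expression,term,value
Immune viability mu/nu > delta,mu/nu - delta,1.0526 (satisfied)
Equilibrium point E1,"E1(Lambda, 0)","E1(10, 0)"
Stability condition of E1,delta/(mu - nu*delta) > Lambda,delta/(mu - nu*delta) = 0.5 <= Lambda = 10 (E1 is unstable)
Equilibrium point E2,"E2(P*, T*)","E2(0.50, 1.71)"
Parameter A1,1 - P*/Lambda,0.9500
Parameter A2,a*P*/(a*P* + 1),0.66667
Least common multiple of order denominators,m,5
Characteristic equation of eigenvalues for E2,"det(diag(L^(m a1), L^(m a2)) - J) = 0",λ^7 - 1.4000*λ^3 + 1.1692 = 0
Eigenvalues for E2,roots,0.9614+0.2454i; 0.9614-0.2454i; 0.1199+1.1495i; 0.1199-1.1495i; -1.2004; -0.4812+0.7135i; -0.4812-0.7135i
Angle of eigenvalues for E2,theta = arg(lambda) [deg],14.3185; -14.3185; 84.0439; -84.0439; 180.0000; 123.9968; -123.9968
Stability condition of E2,|theta_i| > 90/m deg,min |theta| = 14.3185 deg vs 18.0000 deg (E2 is unstable)
Initial conditions,"(P0, T0)","(0.3, 0.01)"
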